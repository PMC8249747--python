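"""Selection engine: library stats, closed-form enrichment, clone sampling."""

import numpy as np
import pytest
from scipy import stats

from gselex.selex import (
    AffinityModel,
    FragmentPool,
    SelexParams,
    bind_scores,
    generate_toy_genome,
    make_fragment_library,
    pool_from_bed,
    pool_to_bed,
    run_selex,
    sample_clones,
    selection_cycle,
)


def two_fragment_pool(L=10_000):
    # fragment 0 covers position 1000; fragment 1 covers 5000
    return FragmentPool(L, np.array([900, 4900]), np.array([300, 300]), np.array([0.5, 0.5]))


class TestLibrary:
    def test_single_fragment_library(self):
        pool = make_fragment_library(10_000, SelexParams(library_size=1, seed=1))
        assert len(pool) == 1 and pool.weight[0] == 1.0

    def test_length_distribution_matches_truncated_normal(self):
        params = SelexParams(library_size=10_000, seed=2)
        pool = make_fragment_library(50_000, params)
        assert abs(pool.length.mean() - 300) < 2
        assert pool.length.min() >= 100 and pool.length.max() <= 600
        assert abs(pool.weight.sum() - 1.0) < 1e-9

    def test_uniform_starts_on_circle(self):
        pool = make_fragment_library(50_000, SelexParams(library_size=20_000, seed=3))
        counts, _ = np.histogram(pool.start, bins=10, range=(0, 50_000))
        assert stats.chisquare(counts).pvalue > 0.01


class TestSelectionCycle:
    def test_background_only_is_identity(self):
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [], background=1.0)
        out = selection_cycle(pool, aff)
        np.testing.assert_allclose(out.weight, pool.weight, atol=1e-12)

    def test_closed_form_three_cycles_single_site(self):
        # site strength 9 over background 1: covering fragment gains (10/1)^k
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [(1000, 9.0)], background=1.0)
        for _ in range(3):
            pool = selection_cycle(pool, aff)
        assert pool.weight[0] / pool.weight[1] == pytest.approx(1000.0, abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_closed_form_two_sites(self, k):
        # strengths 9 and 1: enrichment ratio after k cycles is (10/2)^k
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [(1000, 9.0), (5000, 1.0)], background=1.0)
        for _ in range(k):
            pool = selection_cycle(pool, aff)
        assert pool.weight[0] / pool.weight[1] == pytest.approx(5.0**k, rel=1e-9)

    def test_all_zero_bind_scores_error(self):
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [], background=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            selection_cycle(pool, aff)

    def test_order_invariance_under_permutation(self, rng):
        pool = make_fragment_library(20_000, SelexParams(library_size=500, seed=4))
        aff = AffinityModel.single_state("tf", [(3000, 5.0), (11_000, 2.0)])
        perm = rng.permutation(len(pool))
        permuted = FragmentPool(
            pool.genome_length, pool.start[perm], pool.length[perm], pool.weight[perm]
        )
        np.testing.assert_allclose(
            selection_cycle(permuted, aff).weight,
            selection_cycle(pool, aff).weight[perm],
            rtol=1e-12,
        )

    def test_wrapped_fragment_covers_origin_site(self):
        pool = FragmentPool(1000, np.array([900]), np.array([200]), np.array([1.0]))
        aff = AffinityModel.single_state("tf", [(50, 9.0)])
        assert bind_scores(pool, aff)[0] == pytest.approx(10.0)


class TestRunSelex:
    def test_one_cycle_equals_selection_cycle(self):
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [(1000, 9.0)])
        out1, trace = run_selex(pool, aff, 1)
        out2 = selection_cycle(pool, aff)
        np.testing.assert_allclose(out1.weight, out2.weight)
        assert len(trace) == 1

    def test_strongest_site_mass_nondecreasing(self):
        pool = make_fragment_library(30_000, SelexParams(library_size=2000, seed=5))
        aff = AffinityModel.single_state("tf", [(15_000, 9.0)])
        _, trace = run_selex(pool, aff, 6)
        masses = [t["site_mass"][15_000] for t in trace]
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_weak_site_share_collapses_by_cycle_six(self):
        # closed form: weak/strong fragment weight ratio is (1.5/10)^k < 1%
        pool = two_fragment_pool()
        aff = AffinityModel.single_state("tf", [(1000, 9.0), (5000, 0.5)], background=1.0)
        out, _ = run_selex(pool, aff, 6)
        assert out.weight[1] / out.weight[0] < 0.01
        assert out.weight[1] / out.weight[0] == pytest.approx((1.5 / 10) ** 6, rel=1e-9)

    def test_normalization_after_every_cycle(self):
        pool = make_fragment_library(20_000, SelexParams(library_size=300, seed=6))
        aff = AffinityModel.single_state("tf", [(5000, 9.0)])
        for _ in range(5):
            pool = selection_cycle(pool, aff)
            assert abs(pool.weight.sum() - 1.0) < 1e-9


class TestCloneSampling:
    def test_single_fragment_pool(self):
        pool = FragmentPool(1000, np.array([100]), np.array([300]), np.array([1.0]))
        clones, tally = sample_clones(pool, 5, rng=1)
        assert clones == [(100, 400)] * 5
        assert tally["count"].sum() == 5

    def test_binomial_expectation(self):
        pool = FragmentPool(
            10_000, np.array([0, 5000]), np.array([300, 300]), np.array([0.9, 0.1])
        )
        _, tally = sample_clones(pool, 10_000, rng=42)
        major = int(tally.loc[tally["start"] == 0, "count"].iloc[0])
        sigma = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(major - 9000) <= 3 * sigma

    def test_tally_conserves_clone_count(self, rng):
        pool = make_fragment_library(10_000, SelexParams(library_size=50, seed=7))
        clones, tally = sample_clones(pool, 200, rng=rng)
        assert len(clones) == 200
        assert tally["count"].sum() == 200


class TestToyGenome:
    def test_deterministic_for_fixed_seed(self):
        a1, s1 = generate_toy_genome(2, seed=1)
        a2, s2 = generate_toy_genome(2, seed=1)
        assert s1 == s2
        assert a1.features == a2.features and a1.units == a2.units

    def test_divergent_and_tandem_spacers_present(self):
        from gselex.genome import compute_spacers

        ann, _ = generate_toy_genome(20, seed=8)
        orientations = {s.orientation for s in compute_spacers(ann)}
        assert {"divergent", "tandem"} <= orientations

    def test_base_composition_uniform(self):
        ann, seq = generate_toy_genome(40, seed=9)
        assert len(seq) == ann.length and len(seq) > 50_000
        counts = [seq.count(b) for b in "ACGT"]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rejects_fewer_than_two_units(self):
        with pytest.raises(ValueError):
            generate_toy_genome(1)


def test_pool_bed_round_trip(tmp_path):
    pool = make_fragment_library(10_000, SelexParams(library_size=20, seed=10))
    path = tmp_path / "pool.bed"
    pool_to_bed(pool, path)
    back = pool_from_bed(path)
    assert back.genome_length == pool.genome_length
    np.testing.assert_array_equal(back.start, pool.start)
    np.testing.assert_array_equal(back.length, pool.length)
    np.testing.assert_allclose(back.weight, pool.weight, rtol=1e-10)
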