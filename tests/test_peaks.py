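"""Consecutive-probe peak calling: boundaries, oracle equivalence, decay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gselex.arrays import ArraySignal, design_probes, hybridize
from gselex.peaks import Peak, PeakCallConfig, call_peaks, rank_peaks
from gselex.scenarios import weak_site_scenario
from gselex.selex import SelexParams, make_fragment_library, run_selex


def signal_from(log2_values):
    log2 = np.asarray(log2_values, dtype=float)
    return ArraySignal(2.0**log2, log2, noise_sd=0.0)


def probes_for(n):
    return design_probes(n * 105, probe_len=60, spacing=105)


def brute_force_peaks(log2, threshold, min_run, merge_gap=0):
    """Oracle: enumerate every maximal qualifying run by direct scan."""
    above = [i for i, v in enumerate(log2) if v >= threshold]
    runs = []
    for i in above:
        placed = False
        if runs and i - runs[-1][-1] <= merge_gap + 1:
            runs[-1].append(i)
            placed = True
        if not placed:
            runs.append([i])
    return [(r[0], r[-1]) for r in runs if r[-1] - r[0] + 1 >= min_run]


class TestCallPeaks:
    def test_background_signal_yields_no_peaks(self, rng):
        n = 50
        sig = signal_from(rng.normal(0, 0.05, n))
        assert call_peaks(sig, probes_for(n)) == []

    def test_minimum_run_boundary(self):
        log2 = [0, 0, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 0]
        sig = signal_from(log2)
        probes = probes_for(len(log2))
        peaks6 = call_peaks(sig, probes, PeakCallConfig(min_run=6))
        assert len(peaks6) == 1 and peaks6[0].n_probes == 6
        assert peaks6[0].start == 2 * 105 and peaks6[0].end == 7 * 105 + 60
        assert call_peaks(sig, probes, PeakCallConfig(min_run=7)) == []

    def test_high_vs_minor_level_split(self):
        sig = signal_from([2.5] * 6 + [0] * 2 + [1.2] * 6 + [0])
        peaks = call_peaks(sig, probes_for(15))
        assert [p.level for p in peaks] == ["high", "minor"]

    def test_merge_gap_bridges_subthreshold_probe(self):
        log2 = [1.5, 1.5, 1.5, 0.2, 1.5, 1.5, 1.5, 0]
        sig = signal_from(log2)
        probes = probes_for(len(log2))
        assert call_peaks(sig, probes, PeakCallConfig(min_run=6)) == []
        merged = call_peaks(sig, probes, PeakCallConfig(min_run=6, merge_gap=1))
        assert len(merged) == 1 and merged[0].n_probes == 7

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            call_peaks(signal_from([0] * 5), probes_for(6))

    def test_matches_bruteforce_on_random_signals(self, rng):
        probes = probes_for(80)
        for _ in range(1000):
            log2 = rng.normal(0.7, 0.6, 80)
            cfg = PeakCallConfig(
                log2_threshold=1.0,
                min_run=int(rng.integers(1, 8)),
                merge_gap=int(rng.integers(0, 3)),
            )
            got = [
                (p.start // 105, (p.end - 60) // 105)
                for p in call_peaks(signal_from(log2), probes, cfg)
            ]
            assert got == brute_force_peaks(log2, 1.0, cfg.min_run, cfg.merge_gap)

    @given(st.lists(st.floats(-2, 3, allow_nan=False), min_size=6, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_threshold_and_min_run_monotonicity(self, log2):
        sig = signal_from(log2)
        probes = probes_for(len(log2))
        n_peaks = lambda thr, mr: len(call_peaks(sig, probes, PeakCallConfig(thr, mr)))
        assert n_peaks(1.5, 3) <= n_peaks(1.0, 3)
        assert n_peaks(1.0, 6) <= n_peaks(1.0, 3)

    def test_summit_inside_peak_at_max_probe(self):
        log2 = [0, 1.1, 1.4, 2.8, 1.3, 1.1, 1.2, 0]
        peaks = call_peaks(signal_from(log2), probes_for(8), PeakCallConfig(min_run=6))
        (p,) = peaks
        assert p.start <= p.summit < p.end
        assert p.summit == 3 * 105 + 30  # center of the max-ratio probe


class TestRankPeaks:
    def make(self, pid, start, max_log2):
        return Peak(pid, start, start + 600, start + 300, max_log2, 6, "high")

    def test_single_peak(self):
        p = self.make("a", 0, 2.0)
        assert rank_peaks([p]) == [p]

    def test_descending_by_enrichment(self):
        lo, hi = self.make("lo", 0, 1.2), self.make("hi", 5000, 3.0)
        assert rank_peaks([lo, hi]) == [hi, lo]

    def test_tie_broken_by_position(self):
        a, b = self.make("a", 7000, 2.0), self.make("b", 100, 2.0)
        assert rank_peaks([a, b]) == [b, a]


def test_weak_site_signal_decays_under_competition():
    """A 1.5x nonspecific site loses library mass to a strong site over
    cycles: its probe signal drops and it never reaches a called peak by
    cycle 6, while the strong site's peak persists."""
    scen = weak_site_scenario(seed=5)
    probes = design_probes(scen.ann.length)
    weak_pos = scen.planted_sites["apo"][1][0]
    strong_pos = scen.planted_sites["apo"][0][0]
    near_weak = np.abs(probes.starts + probes.probe_len // 2 - weak_pos) < 400

    def max_log2_near_weak(cycles):
        lib = make_fragment_library(scen.ann, SelexParams(cycles=cycles, seed=5))
        pool, _ = run_selex(lib, scen.aff, cycles)
        sig = hybridize(pool, lib, probes, noise_sd=0.0)
        peaks = call_peaks(sig, probes)
        return float(sig.log2_ratio[near_weak].max()), peaks

    early, _ = max_log2_near_weak(1)
    late, late_peaks = max_log2_near_weak(6)
    assert early > 0.3  # visibly enriched in the early pattern
    assert late < 0  # depleted below the reference by cycle 6
    assert not any(p.start <= weak_pos < p.end for p in late_peaks)
    assert any(p.start <= strong_pos < p.end for p in late_peaks)
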