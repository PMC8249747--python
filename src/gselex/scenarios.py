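"""Canned synthetic study designs used by the examples, tests and pipeline.

Each scenario builds a toy circular genome and plants point binding sites
for one TF at intergenic spacers, mirroring the archetypes seen in genomic
SELEX screens: a single-target factor bound in its own divergent spacer, a
local factor with a couple dozen targets, a conditional single-target
factor whose site list depends on effector state, and a weak nonspecific
site competing with a strong one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import GenomeAnnotation, IntergenicSpacer, compute_spacers
from .selex import AffinityModel, generate_toy_genome


@dataclass
class Scenario:
    name: str
    ann: GenomeAnnotation
    sequence: str
    aff: AffinityModel
    tf_gene: str
    planted_sites: dict  # state -> list[(pos, strength, spacer)]


def _mark_tf_gene(ann: GenomeAnnotation, gene_id: str) -> GenomeAnnotation:
    feats = [replace(f, kind="TF_gene") if f.gene_id == gene_id else f for f in ann.features]
    return GenomeAnnotation(ann.genome_id, ann.length, feats, list(ann.units), ann.circular)


def _candidate_spacers(ann, orientations=("divergent", "tandem"), min_len=200):
    """Non-wrapped spacers of the wanted orientations, widest first."""
    cands = [
        sp
        for sp in compute_spacers(ann)
        if not sp.wraps and sp.orientation in orientations and sp.length >= min_len
    ]
    return sorted(cands, key=lambda sp: -sp.length)


def _disjoint(spacers, n):
    """Greedy pick of spacers with pairwise-disjoint flanking units."""
    used: set[str] = set()
    picked = []
    for sp in spacers:
        if sp.left_unit in used or sp.right_unit in used:
            continue
        picked.append(sp)
        used.update((sp.left_unit, sp.right_unit))
        if len(picked) == n:
            break
    return picked


def _midpoint(sp: IntergenicSpacer) -> int:
    return (sp.start + sp.end) // 2


def single_target_scenario(
    seed=7, n_units=30, strength=9.0, background=1.0
) -> Scenario:
    """One high-affinity site at the center of the TF's own divergent spacer
    (lacI-like autogenous arrangement)."""
    ann, seq = generate_toy_genome(n_units, seed=seed)
    divergent = _candidate_spacers(ann, ("divergent",))
    if not divergent:
        raise ValueError("toy genome has no usable divergent spacer")
    sp = divergent[0]
    site = _midpoint(sp)
    tf_gene = ann.unit(sp.right_unit).genes[0]  # promoter-proximal gene on '+'
    ann = _mark_tf_gene(ann, tf_gene)
    aff = AffinityModel.single_state("TF_st", [(site, strength)], background)
    return Scenario("single_target", ann, seq, aff, tf_gene, {"apo": [(site, strength, sp)]})


def multi_target_scenario(
    seed=7, n_sites=20, n_units=240, strength=9.0, background=1.0
) -> Scenario:
    """Equal-strength sites in ``n_sites`` distinct spacers: a local TF.

    The default genome (~0.6 Mb for 20 sites) keeps the site density within
    an order of magnitude of a real bacterial screen, so that selection is
    not spread so thin that individual loci fall below the consecutive-probe
    criterion."""
    ann, seq = generate_toy_genome(n_units, seed=seed)
    picked = _disjoint(_candidate_spacers(ann), n_sites)
    if len(picked) < n_sites:
        raise ValueError(f"only {len(picked)} usable spacers for {n_sites} sites")
    sites = [(_midpoint(sp), strength) for sp in picked]
    tf_gene = ann.unit(picked[0].right_unit).genes[0]
    ann = _mark_tf_gene(ann, tf_gene)
    aff = AffinityModel.single_state("TF_local", sites, background)
    return Scenario(
        "multi_target",
        ann,
        seq,
        aff,
        tf_gene,
        {"apo": [(p, s, sp) for (p, s), sp in zip(sites, picked)]},
    )


def conditional_scenario(
    seed=7, n_units=150, n_extra=11, strength=9.0, background=1.0
) -> Scenario:
    """Single-target in the apo state; the effector-bound form binds the same
    site plus ``n_extra`` more — the signature of a conditional ST-TF."""
    ann, seq = generate_toy_genome(n_units, seed=seed)
    picked = _disjoint(_candidate_spacers(ann), n_extra + 1)
    if len(picked) < n_extra + 1:
        raise ValueError("toy genome too small for conditional scenario")
    own = next((sp for sp in picked if sp.orientation == "divergent"), picked[0])
    rest = [sp for sp in picked if sp is not own][:n_extra]
    apo_sites = [(_midpoint(own), strength)]
    bound_sites = apo_sites + [(_midpoint(sp), strength) for sp in rest]
    tf_gene = ann.unit(own.right_unit).genes[0]
    ann = _mark_tf_gene(ann, tf_gene)
    aff = AffinityModel(
        "TF_cond",
        {"apo": tuple(apo_sites), "plus_effector": tuple(bound_sites)},
        background,
        state="apo",
    )
    planted = {
        "apo": [(apo_sites[0][0], strength, own)],
        "plus_effector": [(p, s, sp) for (p, s), sp in zip(bound_sites, [own] + rest)],
    }
    return Scenario("conditional", ann, seq, aff, tf_gene, planted)


def weak_site_scenario(
    seed=7, n_units=30, strong=9.0, weak=0.5, background=1.0
) -> Scenario:
    """A strong site plus a weak (nonspecific) one: repeated selection cycles
    drain the weak locus as the strong one soaks up the library."""
    ann, seq = generate_toy_genome(n_units, seed=seed)
    picked = _disjoint(_candidate_spacers(ann), 2)
    if len(picked) < 2:
        raise ValueError("toy genome too small for weak-site scenario")
    strong_sp, weak_sp = picked[0], picked[1]
    sites = [(_midpoint(strong_sp), strong), (_midpoint(weak_sp), weak)]
    tf_gene = ann.unit(strong_sp.right_unit).genes[0]
    ann = _mark_tf_gene(ann, tf_gene)
    aff = AffinityModel.single_state("TF_weak", sites, background)
    return Scenario(
        "weak_site",
        ann,
        seq,
        aff,
        tf_gene,
        {"apo": [(sites[0][0], strong, strong_sp), (sites[1][0], weak, weak_sp)]},
    )


SCENARIOS = {
    "single_target": single_target_scenario,
    "multi_target": multi_target_scenario,
    "conditional": conditional_scenario,
    "weak_site": weak_site_scenario,
}
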