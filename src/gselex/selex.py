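"""Synthetic genomic SELEX: toy genomes, fragment libraries, selection cycles.

The enrichment model is deliberately minimal.  A transcription factor is an
affinity landscape: point binding sites with dimensionless strengths over a
uniform background.  A selection cycle multiplies each fragment's weight by
its bind score — background plus the summed strengths of the sites the
fragment covers — and renormalizes.  Two fragments with bind scores b1, b2
therefore diverge exactly as (b1/b2)^k over k cycles; no amplification bias
or dropout is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneFeature, GenomeAnnotation, TranscriptionUnit


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SelexParams:
    """Library and cycling parameters.

    Fragment lengths are truncated normal on [100, 2*mean] with the stated
    mean and sd (sonication-like ~300 bp segments); starts are uniform on
    the circle.  ``cycles`` is the number of binding/selection rounds,
    typically 3-6 depending on the factor.
    """

    fragment_mean_len: int = 300
    fragment_len_sd: int = 50
    library_size: int = 20_000
    cycles: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.cycles <= 10:
            raise ValueError("cycles must be in [1, 10]")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.fragment_mean_len < 100:
            raise ValueError("fragment_mean_len too small")


@dataclass(frozen=True)
class AffinityModel:
    """A TF's binding sites with strengths, keyed by effector state.

    ``sites_by_state`` maps an effector-state label (e.g. 'apo',
    'plus_effector') to a tuple of (position, strength) point sites;
    ``state`` selects the active list.  ``background`` is the nonspecific
    bind score every fragment receives.
    """

    tf_id: str
    sites_by_state: dict
    background: float = 1.0
    state: str = "apo"

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        for st, sites in self.sites_by_state.items():
            for pos, strength in sites:
                if not np.isfinite(strength) or strength < 0:
                    raise ValueError(f"state {st}: bad site strength {strength}")

    @property
    def sites(self) -> tuple:
        return tuple(self.sites_by_state[self.state])

    def with_state(self, state: str) -> "AffinityModel":
        if state not in self.sites_by_state:
            raise KeyError(f"unknown effector state {state!r}")
        return replace(self, state=state)

    @classmethod
    def single_state(cls, tf_id, sites, background=1.0, state="apo"):
        return cls(tf_id, {state: tuple(sites)}, background, state)


@dataclass
class FragmentPool:
    """Weighted genomic fragments.  ``end`` may exceed the genome length,
    meaning the fragment wraps across the origin."""

    genome_length: int
    start: np.ndarray
    length: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (len(self.start) == len(self.length) == len(self.weight)):
            raise ValueError("ragged fragment arrays")
        if np.any(self.length <= 0):
            raise ValueError("fragment lengths must be positive")
        if np.any(self.weight < 0):
            raise ValueError("negative fragment weight")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    def normalized(self) -> "FragmentPool":
        total = self.weight.sum()
        if total <= 0:
            raise ValueError("pool has zero total weight")
        return FragmentPool(self.genome_length, self.start, self.length, self.weight / total)

    def covers(self, pos: int) -> np.ndarray:
        """Boolean per fragment: does the fragment cover genome position pos?"""
        return (pos - self.start) % self.genome_length < self.length


def make_fragment_library(
    ann_or_length, params: SelexParams, rng=None
) -> FragmentPool:
    """Random sonication-like library: uniform starts, truncated-normal lengths,
    uniform initial weights."""
    L = ann_or_length.length if isinstance(ann_or_length, GenomeAnnotation) else int(ann_or_length)
    rng = as_rng(params.seed if rng is None else rng)
    n = params.library_size
    starts = rng.integers(0, L, size=n)
    m, sd = params.fragment_mean_len, params.fragment_len_sd
    lo, hi = 100, 2 * m
    lengths = stats.truncnorm.rvs(
        (lo - m) / sd, (hi - m) / sd, loc=m, scale=sd, size=n, random_state=rng
    )
    lengths = np.maximum(1, np.rint(lengths).astype(np.int64))
    weights = np.full(n, 1.0 / n)
    return FragmentPool(L, starts, lengths, weights)


def bind_scores(pool: FragmentPool, aff: AffinityModel) -> np.ndarray:
    """Bind score per fragment: background + sum of covered site strengths."""
    b = np.full(len(pool), float(aff.background))
    for pos, strength in aff.sites:
        b += strength * pool.covers(int(pos))
    return b


def selection_cycle(pool: FragmentPool, aff: AffinityModel) -> FragmentPool:
    """One binding/selection round: weight *= bind score, then renormalize."""
    b = bind_scores(pool, aff)
    w = pool.weight * b
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate affinity model: all bind scores zero")
    return FragmentPool(pool.genome_length, pool.start, pool.length, w / total)


def run_selex(pool: FragmentPool, aff: AffinityModel, cycles: int):
    """Iterate selection cycles; returns (pool, trace).

    The trace records, per cycle, the summed weight of fragments covering
    each site (the enrichment trajectory of every planted locus).
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    trace = []
    for k in range(1, cycles + 1):
        pool = selection_cycle(pool, aff)
        site_mass = {
            int(pos): float(pool.weight[pool.covers(int(pos))].sum())
            for pos, _ in aff.sites
        }
        trace.append({"cycle": k, "site_mass": site_mass})
    return pool, trace


def sample_clones(pool: FragmentPool, n: int, rng=None):
    """gSELEX-clos mode: draw n clones multinomially by weight.

    Returns (clones, tally) where clones is a list of (start, end) intervals
    and tally a DataFrame of distinct fragments with their clone counts,
    sorted by count descending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    p = pool.weight / pool.weight.sum()
    counts = rng.multinomial(n, p)
    idx = np.nonzero(counts)[0]
    clones = []
    for i in idx:
        clones.extend([(int(pool.start[i]), int(pool.end[i]))] * int(counts[i]))
    tally = pd.DataFrame(
        {
            "start": pool.start[idx],
            "end": pool.end[idx],
            "count": counts[idx],
        }
    ).sort_values(["count", "start"], ascending=[False, True], ignore_index=True)
    return clones, tally


def clones_overlapping(clones, start: int, end: int, genome_length: int) -> int:
    """Count clones overlapping the (non-wrapped) interval [start, end)."""
    n = 0
    for s, e in clones:
        for s2, e2 in (((s, e), (s - genome_length, e - genome_length)) if e > genome_length else ((s, e),)):
            if min(e2, end) > max(s2, start):
                n += 1
                break
    return n


# -- toy genome generator ------------------------------------------------


DEFAULT_GEOMETRY = {
    "genes_per_unit": (1, 3),
    "gene_len": (600, 1500),
    "spacer_len": (100, 400),
    "intra_gap": (0, 40),
}


def generate_toy_genome(n_units: int, spacer_geometry: dict | None = None, seed=0):
    """Random circular genome with named operons and realistic spacers.

    Strands of the first units are pinned so that at least one divergent
    (and, for n_units >= 3, one tandem) spacer always exists.  Returns
    (GenomeAnnotation, sequence).
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    geo = dict(DEFAULT_GEOMETRY)
    if spacer_geometry:
        geo.update(spacer_geometry)
    rng = as_rng(seed)

    strands = list(rng.choice(["+", "-"], size=n_units))
    strands[0], strands[1] = "-", "+"
    if n_units >= 3:
        strands[2] = "+"

    features: list[GeneFeature] = []
    units: list[TranscriptionUnit] = []
    pos = 0
    gi = 0
    for ui in range(n_units):
        n_genes = int(rng.integers(geo["genes_per_unit"][0], geo["genes_per_unit"][1] + 1))
        member_ids = []
        for j in range(n_genes):
            glen = int(rng.integers(geo["gene_len"][0], geo["gene_len"][1] + 1))
            gid = f"g{gi:04d}"
            features.append(GeneFeature(gid, pos, pos + glen, strands[ui]))
            member_ids.append(gid)
            gi += 1
            pos += glen
            if j < n_genes - 1:
                pos += int(rng.integers(geo["intra_gap"][0], geo["intra_gap"][1] + 1))
        units.append(TranscriptionUnit(f"u{ui:03d}", tuple(member_ids), strands[ui]))
        pos += int(rng.integers(geo["spacer_len"][0], geo["spacer_len"][1] + 1))
    length = pos
    if length <= 0 or features[-1].end > length:
        raise ValueError("geometry cannot fit genome length")
    ann = GenomeAnnotation("toy_genome", length, features, units, circular=True)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)]
    return ann, seq.tobytes().decode()


def pool_to_bed(pool: FragmentPool, path, genome_id="toy_genome") -> None:
    """Export a fragment pool as BED (weight in the score column).

    Wrapped fragments are written with end > genome length; coordinates are
    on the circular genome.
    """
    with open(path, "w") as fh:
        fh.write("# BED: fragment pool (score column = selection weight; circular coords)\n")
        fh.write(f"# genome_length={pool.genome_length}\n")
        for i in range(len(pool)):
            fh.write(
                f"{genome_id}\t{pool.start[i]}\t{pool.end[i]}\tfrag{i:06d}\t"
                f"{pool.weight[i]:.12g}\t.\n"
            )


def pool_from_bed(path) -> FragmentPool:
    starts, lengths, weights = [], [], []
    genome_length = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# genome_length="):
                genome_length = int(line.strip().split("=")[1])
                continue
            if line.startswith("#") or not line.strip():
                continue
            _, s, e, _, w, _ = line.rstrip("\n").split("\t")
            starts.append(int(s))
            lengths.append(int(e) - int(s))
            weights.append(float(w))
    if genome_length is None:
        raise ValueError("pool BED missing # genome_length= header")
    return FragmentPool(genome_length, np.array(starts), np.array(lengths), np.array(weights))
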