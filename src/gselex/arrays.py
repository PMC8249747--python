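"""Tiling-array probe design and two-channel hybridization readout.

Probes are 60-mers laid every 105 bp along the genome (one strand).  The
post-selection pool is the sample channel, the cycle-0 library the
reference channel; the reported statistic is the per-probe sample/reference
ratio (dye labels are metadata).  Probe intensity is overlap-proportional:
each fragment contributes weight * overlap_bp / fragment_len.  Noise is
multiplicative lognormal, the usual shape for two-channel arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selex import FragmentPool, as_rng

EPS = 1e-9


@dataclass(frozen=True)
class ProbeDesign:
    """Regularly spaced probes: probe i covers [i*spacing, i*spacing+probe_len)."""

    genome_len: int
    probe_len: int = 60
    spacing: int = 105

    def __post_init__(self) -> None:
        if self.genome_len < self.probe_len:
            raise ValueError("genome shorter than one probe")
        if not self.probe_len <= self.spacing <= self.genome_len:
            raise ValueError("need probe_len <= spacing <= genome_len")

    @property
    def n_probes(self) -> int:
        return (self.genome_len - self.probe_len) // self.spacing + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_probes, dtype=np.int64) * self.spacing

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.probe_len

    def probe_ids(self) -> list[str]:
        return [f"p{i:06d}" for i in range(self.n_probes)]


def design_probes(genome_len: int, probe_len: int = 60, spacing: int = 105) -> ProbeDesign:
    return ProbeDesign(genome_len, probe_len, spacing)


@dataclass
class ArraySignal:
    """Per-probe sample/reference ratio and its log2."""

    ratio: np.ndarray
    log2_ratio: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=np.float64)
        if len(self.ratio) != len(self.log2_ratio):
            raise ValueError("ragged signal arrays")
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio <= 0):
            raise ValueError("ratios must be finite and positive")

    def __len__(self) -> int:
        return len(self.ratio)


def pool_intensity(pool: FragmentPool, probes: ProbeDesign) -> np.ndarray:
    """Per-probe intensity: sum over overlapping fragments of
    weight * overlap_bp / fragment_len.  Wrapped fragments are split into
    their two linear segments."""
    if len(pool) == 0:
        raise ValueError("empty fragment pool")
    L = pool.genome_length
    starts = pool.start
    ends = pool.end
    wrapped = ends > L
    # linear segments: [start, min(end, L)) and, for wrapped fragments, [0, end-L)
    s1, e1 = starts, np.minimum(ends, L)
    s2, e2 = np.zeros(wrapped.sum(), dtype=np.int64), ends[wrapped] - L
    seg_starts = np.concatenate([s1, s2])
    seg_ends = np.concatenate([e1, e2])
    seg_w = np.concatenate([pool.weight, pool.weight[wrapped]])
    seg_len = np.concatenate([pool.length, pool.length[wrapped]])

    keep = seg_ends > seg_starts
    seg_starts, seg_ends = seg_starts[keep], seg_ends[keep]
    seg_w, seg_len = seg_w[keep], seg_len[keep]

    ps, pl, n = probes.spacing, probes.probe_len, probes.n_probes
    out = np.zeros(n)
    i_min = np.maximum(0, (seg_starts - pl) // ps + 1)
    i_max = np.minimum(n - 1, (seg_ends - 1) // ps)
    span = i_max - i_min
    if len(span) == 0 or span.max() < 0:
        return out
    for k in range(int(span.max()) + 1):
        idx = i_min + k
        valid = (idx <= i_max) & (idx >= 0)
        if not valid.any():
            continue
        p_start = idx * ps
        ov = np.minimum(seg_ends, p_start + pl) - np.maximum(seg_starts, p_start)
        contrib = seg_w * np.maximum(ov, 0) / seg_len
        np.add.at(out, idx[valid], contrib[valid])
    return out


def hybridize(
    pool: FragmentPool,
    ref_pool: FragmentPool,
    probes: ProbeDesign,
    noise_sd: float = 0.0,
    rng=None,
) -> ArraySignal:
    """Two-channel readout: ratio = (sample + eps)/(reference + eps) times
    lognormal noise exp(N(0, noise_sd^2))."""
    sample = pool_intensity(pool.normalized(), probes)
    reference = pool_intensity(ref_pool.normalized(), probes)
    ratio = (sample + EPS) / (reference + EPS)
    if noise_sd > 0:
        rng = as_rng(rng)
        ratio = ratio * np.exp(rng.normal(0.0, noise_sd, size=len(ratio)))
    return ArraySignal(ratio, np.log2(ratio), noise_sd)


def write_probes_bed(probes: ProbeDesign, path, genome_id="toy_genome") -> None:
    with open(path, "w") as fh:
        fh.write("# BED6: tiling probes\n")
        for pid, s, e in zip(probes.probe_ids(), probes.starts, probes.ends):
            fh.write(f"{genome_id}\t{s}\t{e}\t{pid}\t0\t+\n")


def write_signal_tsv(signal: ArraySignal, probes: ProbeDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("# TSV: per-probe two-channel array signal\n")
        fh.write("probe_id\tstart\tend\tratio\tlog2_ratio\n")
        for pid, s, e, r, lr in zip(
            probes.probe_ids(), probes.starts, probes.ends, signal.ratio, signal.log2_ratio
        ):
            fh.write(f"{pid}\t{s}\t{e}\t{r:.10g}\t{lr:.10g}\n")


def read_signal_tsv(path) -> tuple[ArraySignal, np.ndarray, np.ndarray]:
    """Returns (signal, probe_starts, probe_ends)."""
    ratios, log2s, starts, ends = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("probe_id") or not line.strip():
                continue
            _, s, e, r, lr = line.rstrip("\n").split("\t")
            starts.append(int(s))
            ends.append(int(e))
            ratios.append(float(r))
            log2s.append(float(lr))
    return (
        ArraySignal(np.array(ratios), np.array(log2s), noise_sd=float("nan")),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def write_signal_bedgraph(signal: ArraySignal, probes: ProbeDesign, path, genome_id="toy_genome") -> None:
    with open(path, "w") as fh:
        fh.write("track type=bedGraph name=log2_ratio\n")
        for s, e, lr in zip(probes.starts, probes.ends, signal.log2_ratio):
            fh.write(f"{genome_id}\t{s}\t{e}\t{lr:.6g}\n")
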