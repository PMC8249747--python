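"""Peak-to-target annotation: spacer vs ORF context and regulated units.

The peak summit decides context.  A summit in a divergent spacer nominates
both flanking transcription units (one binding site between back-to-back
promoters can control both); a tandem spacer nominates the unit whose
promoter faces the spacer; a convergent spacer faces no promoter and
nominates none.  ORF-internal peaks are recorded but carry no targets —
in the screening they are the supposedly non-specific class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeAnnotation, IntergenicSpacer, compute_spacers, spacer_at
from .peaks import Peak


@dataclass(frozen=True)
class TargetCall:
    peak_id: str
    context: str  # 'spacer' | 'ORF_internal'
    label: str
    target_units: tuple[str, ...]
    spacer_orientation: str | None = None
    level: str = "high"

    def __post_init__(self) -> None:
        if self.context not in ("spacer", "ORF_internal"):
            raise ValueError(f"bad context {self.context!r}")
        if self.context == "ORF_internal" and self.target_units:
            raise ValueError("ORF-internal calls carry no target units")


def assign_target(
    peak: Peak,
    ann: GenomeAnnotation,
    spacers: list[IntergenicSpacer] | None = None,
) -> TargetCall:
    """Map one peak to its genomic context and candidate regulated units."""
    if not 0 <= peak.summit < ann.length:
        raise ValueError("peak summit outside genome")
    gene = ann.gene_at(peak.summit)
    if gene is not None:
        return TargetCall(
            peak.peak_id, "ORF_internal", f"ORF ({gene.gene_id})", (), None, peak.level
        )
    if spacers is None:
        spacers = compute_spacers(ann)
    sp = spacer_at(spacers, peak.summit)
    if sp is None:
        # summit falls between genes of one operon: internal to that unit
        for u in ann.units:
            s, e = ann.unit_extent(u.unit_id)
            if s <= peak.summit < e:
                return TargetCall(
                    peak.peak_id, "ORF_internal", f"ORF ({u.unit_id})", (), None, peak.level
                )
        raise ValueError(f"summit {peak.summit} in unannotated gap with no flanking units")
    label = f"spacer ({sp.left_unit}/{sp.right_unit})"
    if sp.orientation == "divergent":
        targets = (sp.left_unit, sp.right_unit)
    elif sp.orientation == "tandem":
        # the downstream-facing unit whose promoter side abuts the spacer
        strand = ann.unit(sp.left_unit).strand  # tandem: both strands equal
        targets = (sp.right_unit,) if strand == "+" else (sp.left_unit,)
    else:  # convergent: no promoters face the spacer
        targets = ()
    return TargetCall(peak.peak_id, "spacer", label, targets, sp.orientation, peak.level)


def annotate_peaks(peaks: list[Peak], ann: GenomeAnnotation) -> list[TargetCall]:
    spacers = compute_spacers(ann)
    return [assign_target(p, ann, spacers) for p in peaks]


def count_distinct_targets(
    calls: list[TargetCall],
    restrict_level: str | None = "high",
    collapse_divergent: bool = True,
) -> int:
    """Number of distinct regulated loci across the calls of one TF run.

    With ``collapse_divergent`` (default) a divergent pair controlled from a
    single spacer counts as one regulatory locus — the convention under
    which a factor binding one bidirectional spacer is a single-target TF.
    Pass ``collapse_divergent=False`` for per-unit counting.
    """
    kept = [
        c
        for c in calls
        if c.target_units and (restrict_level is None or c.level == restrict_level)
    ]
    if not kept:
        return 0
    units = sorted({u for c in kept for u in c.target_units})
    if not collapse_divergent:
        return len(units)
    # union-find: each call's target set forms one locus
    parent = {u: u for u in units}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for c in kept:
        root = find(c.target_units[0])
        for u in c.target_units[1:]:
            parent[find(u)] = root
    return len({find(u) for u in units})


def write_targets_tsv(calls: list[TargetCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("# TSV: peak target annotation\n")
        fh.write("peak_id\tcontext\torientation\tlabel\ttarget_units\tlevel\n")
        for c in calls:
            fh.write(
                f"{c.peak_id}\t{c.context}\t{c.spacer_orientation or '.'}\t{c.label}\t"
                f"{','.join(c.target_units) or '.'}\t{c.level}\n"
            )


def read_targets_tsv(path) -> list[TargetCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("peak_id") or not line.strip():
                continue
            pid, ctx, ori, label, units, level = line.rstrip("\n").split("\t")
            calls.append(
                TargetCall(
                    pid,
                    ctx,
                    label,
                    tuple(units.split(",")) if units != "." else (),
                    None if ori == "." else ori,
                    level,
                )
            )
    return calls
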