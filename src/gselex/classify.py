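"""TF classification: regulon-size groups, gene organization, ST-TF registry.

Factors are grouped by the number of regulatory targets their screen
identifies: single-target (1 to several), local (tens), global (hundreds)
and nucleoid-associated (binding sites numbering toward a thousand).  The
published bands do not partition the integers, so counts falling in the
gaps get an explicit ``intermediate`` label rather than forced membership.

Gene organization: ``type_A`` when the TF gene sits adjacent to its target
genes (same unit, or sharing an intergenic spacer — the lacI/lacZYA
arrangement), ``type_B`` when TF gene and targets are separated on the
genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .genome import GenomeAnnotation, compute_spacers


@dataclass(frozen=True)
class ClassificationThresholds:
    """Regulon-size bands.  Defaults render 'one to several' as 1-3 targets,
    local as 10-50, global as >=100; nucleoid-associated factors are keyed
    on binding-site count (>=500) rather than regulated units."""

    st_max: int = 3
    local_min: int = 10
    local_max: int = 50
    global_min: int = 100
    nap_min: int = 500

    def __post_init__(self) -> None:
        if not (self.st_max < self.local_min <= self.local_max < self.global_min <= self.nap_min):
            raise ValueError("thresholds must satisfy st_max < local_min <= local_max < global_min <= nap_min")


@dataclass(frozen=True)
class TFClassification:
    tf_id: str
    effector_state: str
    n_targets: int
    group: str  # ST | local | global | NAP | intermediate | none
    conditional_st: bool = False


@dataclass(frozen=True)
class GeneOrgLabel:
    tf_id: str
    org: str  # type_A | type_B
    evidence: str
    separation_bp: int | None = None


@dataclass(frozen=True)
class STTFRegistryEntry:
    tf_name: str
    alternative_name: str
    family: str
    org: str
    effector: str
    function: str
    target_operons: str
    version: int
    discrepant: bool = False
    note: str = ""


def classify_tf(
    n_targets: int,
    n_sites: int = 0,
    th: ClassificationThresholds | None = None,
    tf_id: str = "TF",
    effector_state: str = "apo",
) -> TFClassification:
    """Total classification on non-negative counts: exactly one label."""
    th = th or ClassificationThresholds()
    if n_targets < 0 or n_sites < 0:
        raise ValueError("counts must be non-negative")
    if n_sites >= th.nap_min:
        group = "NAP"
    elif n_targets >= th.global_min:
        group = "global"
    elif th.local_min <= n_targets <= th.local_max:
        group = "local"
    elif 1 <= n_targets <= th.st_max:
        group = "ST"
    elif n_targets == 0:
        group = "none"
    else:
        group = "intermediate"
    return TFClassification(tf_id, effector_state, n_targets, group)


def classify_conditional(runs: list[TFClassification]) -> TFClassification:
    """Combine per-effector-state classifications for one TF.

    A factor that is single-target in exactly one state and not in another
    is a conditional ST-TF; the reported classification is that of the
    functional (single-target) state.
    """
    if not runs:
        raise ValueError("no classifications given")
    if len(runs) == 1:
        return runs[0]
    st_runs = [r for r in runs if r.group == "ST"]
    non_st = [r for r in runs if r.group != "ST"]
    if len(st_runs) == 1 and non_st:
        r = st_runs[0]
        return TFClassification(r.tf_id, r.effector_state, r.n_targets, "ST", conditional_st=True)
    if st_runs and not non_st:  # ST in every state: unconditional
        r = st_runs[0]
        return TFClassification(r.tf_id, r.effector_state, r.n_targets, "ST", conditional_st=False)
    # no state (or several states plus several non-ST): report the smallest regulon
    r = min(runs, key=lambda x: x.n_targets)
    return TFClassification(r.tf_id, r.effector_state, r.n_targets, r.group, conditional_st=False)


def classify_gene_org(
    tf_gene: str, target_units: list[str], ann: GenomeAnnotation
) -> GeneOrgLabel:
    """type_A iff the TF gene's unit is itself a target or shares a spacer
    with one; otherwise type_B with the minimal separation recorded."""
    tf_unit = ann.unit_of_gene(tf_gene)
    for u in target_units:
        if u not in {x.unit_id for x in ann.units}:
            raise ValueError(f"target unit {u} absent from annotation")
    targets = set(target_units)
    if tf_unit in targets:
        return GeneOrgLabel(tf_gene, "type_A", f"TF unit {tf_unit} is itself a target")
    for sp in compute_spacers(ann):
        pair = {sp.left_unit, sp.right_unit}
        if tf_unit in pair and pair & targets:
            other = (pair - {tf_unit}).pop()
            return GeneOrgLabel(
                tf_gene, "type_A", f"TF unit {tf_unit} shares spacer with target {other}"
            )
    if not targets:
        return GeneOrgLabel(tf_gene, "type_B", "no target units identified", None)
    L = ann.length
    ts, te = ann.unit_extent(tf_unit)
    best = None
    for u in targets:
        us, ue = ann.unit_extent(u)
        d = min((us - te) % L, (ts - ue) % L)
        best = d if best is None else min(best, d)
    return GeneOrgLabel(
        tf_gene, "type_B", f"TF unit {tf_unit} separated from nearest target", int(best)
    )


def load_registry(include_discrepant: bool = False) -> list[STTFRegistryEntry]:
    """The packaged single-target TF registry.

    Version 1 is the previously published thirteen (BetI ... XynR); version 2
    the eleven reported alongside this screen (CsqR ... YqhC).  Rows flagged
    discrepant record table/text inconsistencies and are excluded unless
    requested.
    """
    with resources.files("gselex.data").joinpath("st_tf_registry.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            STTFRegistryEntry(
                tf_name=row["tf_name"],
                alternative_name=row["alternative_name"],
                family=row["family"],
                org=row["org"],
                effector=row["effector"],
                function=row["function"],
                target_operons=row["target_operons"],
                version=int(row["version"]),
                discrepant=row["discrepant"] == "1",
                note=row["note"],
            )
        )
    names = [e.tf_name for e in entries]
    if len(names) != len(set(names)):
        raise ValueError("duplicate TF names in registry")
    for e in entries:
        if e.version not in (1, 2):
            raise ValueError(f"{e.tf_name}: bad registry version {e.version}")
        if e.org not in ("type_A", "type_B"):
            raise ValueError(f"{e.tf_name}: bad org label {e.org}")
    if not include_discrepant:
        entries = [e for e in entries if not e.discrepant]
    return entries


def registry_counts(entries: list[STTFRegistryEntry] | None = None) -> dict:
    """Summary counts over the packaged registry (discrepant rows excluded)."""
    entries = entries if entries is not None else load_registry()
    by_version = {v: sum(e.version == v for e in entries) for v in (1, 2)}
    by_org = {
        org: sum(e.org == org for e in entries) for org in ("type_A", "type_B")
    }
    return {
        "total": len(entries),
        "by_version": by_version,
        "by_org": by_org,
        "version1_type_A": sum(e.version == 1 and e.org == "type_A" for e in entries),
        "version2_type_A": sum(e.version == 2 and e.org == "type_A" for e in entries),
    }
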