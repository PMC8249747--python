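"""End-to-end orchestration: genome -> SELEX -> array -> peaks -> targets ->
classification, as one seeded, logged, reproducible run."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arrays import (
    ProbeDesign,
    design_probes,
    hybridize,
    write_probes_bed,
    write_signal_bedgraph,
    write_signal_tsv,
)
from .classify import (
    ClassificationThresholds,
    TFClassification,
    classify_conditional,
    classify_gene_org,
    classify_tf,
    registry_counts,
)
from .genome import GenomeAnnotation, write_annotation
from .peaks import PeakCallConfig, call_peaks, write_peaks_bed, write_peaks_tsv
from .scenarios import SCENARIOS, Scenario
from .selex import AffinityModel, FragmentPool, SelexParams, make_fragment_library, run_selex
from .targets import annotate_peaks, count_distinct_targets, write_targets_tsv


@dataclass
class AssayResult:
    """Everything one TF/effector-state screen produces."""

    state: str
    library: FragmentPool
    pool: FragmentPool
    trace: list
    signal: object
    peaks: list
    calls: list
    n_targets: int


def run_tf_assay(
    ann: GenomeAnnotation,
    aff: AffinityModel,
    selex_params: SelexParams,
    probes: ProbeDesign | None = None,
    noise_sd: float = 0.1,
    peak_cfg: PeakCallConfig | None = None,
    seed: int = 0,
) -> AssayResult:
    """One complete in-silico screen for the affinity model's current state."""
    probes = probes or design_probes(ann.length)
    ss = np.random.SeedSequence(seed)
    rng_lib, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    library = make_fragment_library(ann, selex_params, rng=rng_lib)
    pool, trace = run_selex(library, aff, selex_params.cycles)
    signal = hybridize(pool, library, probes, noise_sd=noise_sd, rng=rng_noise)
    peaks = call_peaks(signal, probes, peak_cfg)
    calls = annotate_peaks(peaks, ann)
    n_targets = count_distinct_targets(calls)
    return AssayResult(aff.state, library, pool, trace, signal, peaks, calls, n_targets)


@dataclass
class PipelineConfig:
    """One reproducible run: scenario, library, array, calling, thresholds."""

    scenario: str = "single_target"
    scenario_params: dict = field(default_factory=dict)
    fragment_mean_len: int = 300
    fragment_len_sd: int = 50
    library_size: int = 20_000
    cycles: int = 4
    probe_len: int = 60
    spacing: int = 105
    noise_sd: float = 0.1
    log2_threshold: float = 1.0
    min_run: int = 6
    merge_gap: int = 0
    st_max: int = 3
    local_min: int = 10
    local_max: int = 50
    global_min: int = 100
    nap_min: int = 500
    seed: int = 7
    output_dir: str = "gselex_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def selex_params(self) -> SelexParams:
        return SelexParams(
            self.fragment_mean_len, self.fragment_len_sd, self.library_size, self.cycles, self.seed
        )

    def peak_cfg(self) -> PeakCallConfig:
        return PeakCallConfig(self.log2_threshold, self.min_run, self.merge_gap)

    def thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(
            self.st_max, self.local_min, self.local_max, self.global_min, self.nap_min
        )


def run_pipeline(cfg: PipelineConfig, quiet: bool = True) -> dict:
    """Run the configured scenario end to end and write the report bundle.

    Outputs: genome FASTA/GFF3, probe BED, per-state signal TSV/bedGraph,
    peak BED/TSV, target TSV, classification JSON and a run manifest.
    Re-running with the same config reproduces every file byte for byte.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if not quiet:
            print(f"[gselex +{time.time() - t0:6.2f}s] {msg}", file=sys.stderr)

    if cfg.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {cfg.scenario!r}; options: {sorted(SCENARIOS)}")
    scen: Scenario = SCENARIOS[cfg.scenario](seed=cfg.seed, **cfg.scenario_params)
    log(f"scenario {cfg.scenario}: genome {scen.ann.length} bp, TF gene {scen.tf_gene}")
    write_annotation(scen.ann, out / "genome.gff3", out / "genome.fasta", scen.sequence)

    probes = design_probes(scen.ann.length, cfg.probe_len, cfg.spacing)
    write_probes_bed(probes, out / "probes.bed", scen.ann.genome_id)

    per_state: dict[str, TFClassification] = {}
    state_reports = {}
    for i, state in enumerate(sorted(scen.aff.sites_by_state)):
        aff = scen.aff.with_state(state)
        res = run_tf_assay(
            scen.ann,
            aff,
            cfg.selex_params(),
            probes=probes,
            noise_sd=cfg.noise_sd,
            peak_cfg=cfg.peak_cfg(),
            seed=cfg.seed + i,
        )
        log(f"state {state}: {len(res.peaks)} peaks, {res.n_targets} targets")
        sdir = out / f"state_{state}"
        sdir.mkdir(exist_ok=True)
        write_signal_tsv(res.signal, probes, sdir / "signal.tsv")
        write_signal_bedgraph(res.signal, probes, sdir / "signal.bedgraph", scen.ann.genome_id)
        write_peaks_tsv(res.peaks, sdir / "peaks.tsv")
        write_peaks_bed(res.peaks, sdir / "peaks.bed", scen.ann.genome_id)
        write_targets_tsv(res.calls, sdir / "targets.tsv")
        cls = classify_tf(
            res.n_targets,
            n_sites=len(res.peaks),
            th=cfg.thresholds(),
            tf_id=scen.aff.tf_id,
            effector_state=state,
        )
        per_state[state] = cls
        target_units = sorted({u for c in res.calls if c.level == "high" for u in c.target_units})
        state_reports[state] = {
            "n_peaks": len(res.peaks),
            "n_targets": res.n_targets,
            "group": cls.group,
            "target_units": target_units,
        }

    combined = classify_conditional(list(per_state.values()))
    org_units = state_reports[combined.effector_state]["target_units"]
    org = classify_gene_org(scen.tf_gene, list(org_units), scen.ann)

    classification = {
        "tf_id": scen.aff.tf_id,
        "tf_gene": scen.tf_gene,
        "states": state_reports,
        "group": combined.group,
        "n_targets": combined.n_targets,
        "conditional_st": combined.conditional_st,
        "gene_org": org.org,
        "gene_org_evidence": org.evidence,
        "separation_bp": org.separation_bp,
    }
    (out / "classification.json").write_text(json.dumps(classification, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "gselex_version": __version__,
        "outputs": sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log("done")
    return classification


def registry_report() -> dict:
    """Counts over the packaged single-target TF registry."""
    return registry_counts()
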