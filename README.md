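# gselex

A laboratory-in-software for **genomic SELEX screening** of bacterial
transcription-factor (TF) binding sites, with the downstream analysis used to
discover *single-target transcription factors* (ST-TFs).

In the wet experiment, a purified TF is mixed with a library of ~300-bp
genomic DNA fragments; bound fragments are recovered and re-amplified over
3–6 selection cycles, then hybridized against the starting library on a
tiling microarray (60-bp probes every 105 bp). A genuine binding site shows
up as a run of at least six consecutive elevated probes, whose location —
intergenic spacer vs. ORF, divergent vs. tandem promoters — identifies the
regulated transcription units. Counting distinct targets classifies each TF
as single-target (1 to a few targets), local (~10–50), global (>100) or
nucleoid-associated (~1,000 binding sites), and comparing the TF gene's
position with its targets labels the pair *type-A* (adjacent, lacI/lacZYA
style) or *type-B* (separated).

This package implements every stage as a tested, seeded simulation plus
reusable analysis code:

- **`gselex.genome`** — circular genome annotation (GFF3/FASTA I/O),
  transcription units, intergenic spacers with orientation.
- **`gselex.selex`** — toy genome generator, fragment library, multiplicative
  selection cycles (weight ∝ bind score *b* = background + Σ covered site
  strengths; two fragments diverge exactly as (*b₁/b₂*)ᵏ over *k* cycles),
  clone-and-sequence sampling.
- **`gselex.arrays`** — probe design and two-channel readout: per-probe
  ratio = sample/reference intensity with lognormal noise.
- **`gselex.peaks`** — consecutive-probe peak caller (threshold on log2
  ratio, minimum run length, optional gap bridging) with high/minor levels.
- **`gselex.targets`** — summit-based context assignment and distinct-target
  counting (a divergent pair regulated from one spacer counts once).
- **`gselex.classify`** — regulon-size groups, conditional ST-TF logic,
  type-A/type-B gene organization, and the packaged 24-entry ST-TF registry.
- **`gselex.motifs`** — IUPAC degenerate motif search (e.g. the palindromic
  RspR-box `ATACNNGTAT`), palindrome test, DNase-I footprint bookkeeping.
- **`gselex.pipeline` / `gselex` CLI** — one seeded, reproducible run from
  genome to classification JSON.

## Worked example

```bash
python examples/01_single_target_screen.py
```

prints (seed 7):

```
genome: 75,252 bp, 30 transcription units
planted site: position 67772, strength 9.0, in the divergent spacer u026/u027

called peaks (1):
  peak_000: [67410, 68100) 7 probes, max log2 ratio 8.16 (high)
  -> spacer (u026/u027) targets=['u026', 'u027']

distinct regulatory loci: 1  -> group ST
gene organization: type_A (TF unit u027 is itself a target)
```

One planted high-affinity site yields one peak spanning 7 consecutive probes
(the ~2×300-bp fragment pileup at 105-bp spacing), annotated to the
divergent spacer whose two flanking units count as a single regulatory
locus; the factor is classified single-target with type-A organization
(it sits next to — here, among — its own targets). The same run is available
as a shell command with a full report bundle:

```bash
gselex run-all --seed 7 --out demo_run
gselex registry            # the packaged ST-TF registry and its counts
```

Other examples cover the conditional ST-TF two-state screen, the registry
report, motif/footprint analysis, and clone-sequencing readout.

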