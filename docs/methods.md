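# Methods

## The model

### Genome and annotation

Genomes are circular with 0-based half-open internal coordinates. Genes are
point-strand intervals grouped into transcription units (operons) taken from
an explicit `operon` attribute in GFF3 — no operon prediction is attempted,
because unit membership is treated as known annotation. Adjacent units
separated by ≥1 bp define an intergenic spacer whose orientation follows the
flanking strands: `(−,+)` divergent (two back-to-back promoters face the
spacer), `(+,−)` convergent (no promoter faces it), same-strand tandem (one
promoter faces it). Features may not span the replication origin; spacers and
fragments may wrap (`wraps=True`, or fragment `end >` genome length). GFF3 is
written 1-based inclusive and BED 0-based half-open, the standard dialects,
so external tools interoperate bit-exactly.

### Selection dynamics

A TF is an affinity landscape: point sites `(position, strength)` over a
uniform background `b₀ > 0`, optionally keyed by effector state (alternative
site lists model phosphorylation/ligand-dependent binding). A fragment's
bind score is

    b = b₀ + Σ strength(site)   over sites whose position lies inside the fragment

and one selection cycle multiplies each fragment's weight by `b` and
renormalizes. The fragment set never changes; there is no amplification bias
or dropout (no parameters for either are available). Consequences used as
oracles throughout the tests:

- background-only selection is the identity;
- two fragments with scores `b₁, b₂` satisfy `w₁/w₂ = (b₁/b₂)^k` after `k`
  cycles, exactly (floating tolerance 1e-9);
- a weak site (score 1.5) competing with a strong one (score 10) falls to
  `(1.5/10)^k` of the strong locus — below 1% by cycle 3 — reproducing the
  early-cycle appearance and later disappearance of nonspecific loci.

The fragment library has uniform starts on the circle and truncated-normal
lengths on `[100, 2·mean]` (mean 300 bp, sd 50 bp), a sonication-like shape.
Library size defaults to 20,000 fragments, chosen once as a realistic depth
(several-hundred-fold site coverage at the toy-genome scales used here).

Clone-sequencing mode (`sample_clones`) draws n fragments multinomially by
weight and tallies them by locus.

### Array readout

Probes are 60-mers every 105 bp on one strand; probe count is derived as
`(L − 60) // 105 + 1`. Per-probe intensity is overlap-proportional:
`Σ weight · overlap_bp / fragment_len` over overlapping fragments, so a
fragment's mass is distributed linearly across the probes it touches. The
reported statistic is `ratio = (sample + ε)/(reference + ε)` (ε = 1e-9) with
the post-selection pool as sample and the cycle-0 library as reference —
dye names are metadata, the semantics are fixed as sample/reference. Noise
is multiplicative lognormal `exp(N(0, σ²))`, the usual two-channel shape;
σ defaults to 0.1 (≈0.14 in log2 units).

### Peak calling

A peak is a maximal run of probes with `log2(ratio) ≥` threshold, optionally
bridging up to `merge_gap` sub-threshold probes; runs shorter than `min_run`
probes are discarded. Defaults: threshold 1.0 (conventional 2-fold — the
source analysis names no numeric cut-off), `min_run` 6, `merge_gap` 0.
Fragments of ~300 bp pile up over a point site across roughly twice the
fragment length, i.e. ≈600 bp ≈ 6 probes at 105-bp spacing; the zero-noise
run length on the default single-site fixture is 6–7 probes, which is why
"at least six consecutive probes" is the validity criterion and why
`min_run = 6` interprets it as run length ≥ 6 (a strict > 6 would reject the
geometry that motivates it). Peaks with max log2 at least twice the
threshold are `high`, the rest `minor`. The summit is the center of the
maximum-ratio probe.

### Target assignment and counting

The summit (not the peak extent, which can overhang gene ends) decides
context. Divergent spacer → both flanking units are candidate targets;
tandem → the unit whose promoter abuts the spacer; convergent → none;
inside a gene (or in an intra-operon gap) → `ORF_internal` with no targets,
recorded but excluded from counts as the supposedly-nonspecific class.
`count_distinct_targets` counts distinct regulatory loci over high-level
peaks by default, merging the units of one divergent call into a single
locus (union-find over per-call target sets) — the convention under which a
factor binding one bidirectional spacer is single-target; per-unit counting
and minor-peak inclusion are flags.

### Classification

Groups by target count: ST for 1–3 (`st_max = 3` renders "one to several"),
local for 10–50, global for ≥100, NAP when the *binding-site* count (called
peaks) reaches 500 — NAPs are bookkept by sites, not regulated units. Counts
in the unstated gaps (4–9, 51–99) are labeled `intermediate`; zero targets is
`none`. A TF screened in several effector states is a *conditional* ST-TF
when exactly one state is ST and another is not; the reported classification
is that of the single-target (functional) form.

Gene organization: `type_A` iff the TF gene's unit is itself a target or
shares a spacer with one — adjacency, with no base-pair cutoff, since every
adjacent case in the registry satisfies it and the one quantified separated
case is ~26 kb away; otherwise `type_B` with the minimal circular separation
recorded.

### Registry

`gselex/data/st_tf_registry.tsv` transcribes the printed single-target TF
lists: 13 version-1 entries (BetI, CecR, DecR, KdpE, LacI, MarR, NanR, NimR,
RpiR, TorR, UlaR, UxuR, XynR) and 11 version-2 entries (CsqR, CusR, HprR,
NorR, PepA, PutA, QseA, RspR, UvrY, ZraR, YqhC); type-B = {DecR, PepA, RspR,
UvrY}. Known source inconsistencies are carried as data rather than
resolved silently: NemR appears only in the printed table and is flagged
`discrepant` (excluded from counts, which follow the stated totals of 24 =
13 + 11); the XynR/XylR and CsqR/CsgR spelling variants are recorded in the
`note` column.

### Motif tools

IUPAC search compiles the degenerate pattern to a character-class regex
inside a lookahead, so overlapping matches are all reported; minus-strand
hits are matches of the reverse-complement pattern reported at plus-strand
coordinates. A pattern is palindromic iff it equals its IUPAC reverse
complement (N ↔ N), so `ATACNNGTAT` is a palindrome and matches each
occurrence on both strands at the same start. Footprints are intervals with
hypersensitive positions; `footprint_overlap` reports containment and the
offset of each hit's center from the footprint center.

## Synthetic scenarios: what they emulate, and what they don't

`gselex.scenarios` packages four study designs: a single site in the TF's
own divergent spacer (autogenous single-target), twenty equal-strength sites
in distinct spacers (local TF), a two-state conditional design (one site
apo, twelve with effector), and a strong-plus-weak pair (nonspecific decay).
Toy genomes default to ~75 kb (30 units) for single-site designs and
~0.6 Mb (240 units) for the 20-site design: per-site enrichment scales with
genome length divided by total site-covering mass, and 0.6 Mb keeps the
site density within an order of magnitude of a real ~4.6-Mb screen, so
individual loci are not diluted below the consecutive-probe criterion.
Scenario site placement prefers the widest eligible spacers (≥200 bp) so
summits stay inside spacers under probe-granularity jitter.

The generator emulates coverage pileup, multiplicative selection, and
two-channel ratio noise. It does **not** emulate sequence-dependent
affinity (no PWMs), PCR bias, dye bias, replicate arrays, cross-hybridization,
or repeat structure; uniform random sequence also means motif searches on
toy genomes have Poisson hit statistics only. Passing recovery tests
therefore demonstrate the correctness of the analysis chain under the stated
enrichment model, not performance on real array data.

## Numerical and design choices

- All randomness flows from one integer seed per run; stages draw from
  `numpy` Generators spawned via `SeedSequence` in a fixed order, so reruns
  are byte-identical (the pipeline manifest lists config, seed and outputs;
  no timestamps are written).
- Weight normalization is enforced to |Σw − 1| < 1e-9 after every cycle;
  hybridization adds ε = 1e-9 to both channels to keep ratios finite.
- Peak ties in ranking break toward the lower genomic coordinate.
- Degenerate inputs fail loudly: all-zero bind scores, empty pools, genomes
  shorter than one probe, summits outside the genome, malformed thresholds.

## Known limitations

- A 1.5× bind score (the weak-site design) caps its cycle-1 probe signal at
  log2 1.5 ≈ 0.58, below the default 2-fold calling threshold; early-cycle
  nonspecific loci are therefore visible in the signal track but not as
  called peaks under defaults. The decay behavior is asserted at signal
  level in the test suite.
- Features spanning the origin are unsupported (v1); rotate the annotation
  origin into a spacer if needed.
- The probe-mixture design of the real 43,450-feature array is not modeled;
  probe count here derives from genome length and spacing.
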