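"""Annotated circular bacterial genome: genes, transcription units, spacers.

Internal coordinates are 0-based half-open throughout.  GFF3 is written
1-based inclusive and BED 0-based half-open, the standard dialects for each
format.  Features may not span the replication origin; intergenic spacers
may wrap around it (``wraps=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

GENE_KINDS = {"ORF", "TF_gene", "prophage", "sRNA"}
ORIENTATIONS = ("divergent", "convergent", "tandem")


@dataclass(frozen=True)
class GeneFeature:
    """A gene on the genome, 0-based half-open, strand '+' or '-'."""

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "ORF"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.gene_id}: bad kind {self.kind!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptionUnit:
    """An operon: contiguous, same-strand member genes, in genomic order.

    The promoter sits at the 5' end of the unit (left boundary on '+',
    right boundary on '-').
    """

    unit_id: str
    genes: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"unit {self.unit_id}: no member genes")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unit {self.unit_id}: bad strand")


@dataclass(frozen=True)
class IntergenicSpacer:
    """Gap between two adjacent transcription units.

    ``orientation`` is divergent when two promoters face the spacer
    back-to-back (left unit on '-', right on '+'), convergent when both
    units point into it, tandem otherwise.  A spacer crossing the origin
    of a circular genome has ``wraps=True`` and ``end <= start``.
    """

    left_unit: str
    right_unit: str
    start: int
    end: int
    orientation: str
    length: int
    wraps: bool = False

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end


@dataclass
class GenomeAnnotation:
    """Genome length plus gene features grouped into transcription units."""

    genome_id: str
    length: int
    features: list[GeneFeature]
    units: list[TranscriptionUnit]
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        self.features = sorted(self.features, key=lambda f: f.start)
        seen: set[str] = set()
        prev: GeneFeature | None = None
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)
            if not (0 <= f.start < f.end <= self.length):
                raise ValueError(f"gene {f.gene_id} outside [0, {self.length})")
            if prev is not None and f.start < prev.end and f.strand == prev.strand:
                warnings.warn(
                    f"overlapping same-strand genes {prev.gene_id}/{f.gene_id}",
                    stacklevel=2,
                )
            prev = f
        self._by_gene = {f.gene_id: f for f in self.features}
        self._unit_of_gene: dict[str, str] = {}
        for u in self.units:
            for g in u.genes:
                if g not in self._by_gene:
                    raise ValueError(f"unit {u.unit_id} references unknown gene {g}")
                if g in self._unit_of_gene:
                    raise ValueError(f"gene {g} in more than one unit")
                if self._by_gene[g].strand != u.strand:
                    raise ValueError(f"unit {u.unit_id}: strand mismatch for {g}")
                self._unit_of_gene[g] = u.unit_id
        orphans = seen - set(self._unit_of_gene)
        if orphans:
            raise ValueError(f"genes not assigned to any unit: {sorted(orphans)}")
        self._units_by_id = {u.unit_id: u for u in self.units}

    # -- lookups -------------------------------------------------------

    def gene(self, gene_id: str) -> GeneFeature:
        return self._by_gene[gene_id]

    def unit(self, unit_id: str) -> TranscriptionUnit:
        return self._units_by_id[unit_id]

    def unit_of_gene(self, gene_id: str) -> str:
        return self._unit_of_gene[gene_id]

    def unit_extent(self, unit_id: str) -> tuple[int, int]:
        u = self._units_by_id[unit_id]
        starts = [self._by_gene[g].start for g in u.genes]
        ends = [self._by_gene[g].end for g in u.genes]
        return min(starts), max(ends)

    def promoter_pos(self, unit_id: str) -> int:
        """Transcription-start-side boundary of the unit (5' end)."""
        s, e = self.unit_extent(unit_id)
        return s if self._units_by_id[unit_id].strand == "+" else e

    def gene_at(self, pos: int) -> GeneFeature | None:
        for f in self.features:  # genomes here are small; linear scan is fine
            if f.contains(pos):
                return f
        return None

    def units_sorted(self) -> list[TranscriptionUnit]:
        return sorted(self.units, key=lambda u: self.unit_extent(u.unit_id)[0])


def compute_spacers(ann: GenomeAnnotation) -> list[IntergenicSpacer]:
    """One spacer per adjacent unit pair separated by >= 1 bp.

    Abutting or overlapping units yield no spacer.  On a circular genome
    the (last, first) pair yields one wrapped spacer.
    """
    units = ann.units_sorted()
    if len(units) < 2:
        return []
    spacers: list[IntergenicSpacer] = []
    pairs = list(zip(units, units[1:]))
    for left, right in pairs:
        ls, le = ann.unit_extent(left.unit_id)
        rs, re = ann.unit_extent(right.unit_id)
        gap = rs - le
        if gap >= 1:
            spacers.append(
                IntergenicSpacer(
                    left.unit_id,
                    right.unit_id,
                    le,
                    rs,
                    _orientation(left.strand, right.strand),
                    gap,
                )
            )
    if ann.circular:
        last, first = units[-1], units[0]
        le = ann.unit_extent(last.unit_id)[1]
        fs = ann.unit_extent(first.unit_id)[0]
        gap = (fs - le) % ann.length
        if gap >= 1 and last.unit_id != first.unit_id:
            spacers.append(
                IntergenicSpacer(
                    last.unit_id,
                    first.unit_id,
                    le,
                    fs,
                    _orientation(last.strand, first.strand),
                    gap,
                    wraps=True,
                )
            )
    return spacers


def _orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == "-" and right_strand == "+":
        return "divergent"
    if left_strand == "+" and right_strand == "-":
        return "convergent"
    return "tandem"


def spacer_at(spacers: list[IntergenicSpacer], pos: int) -> IntergenicSpacer | None:
    for sp in spacers:
        if sp.contains(pos):
            return sp
    return None


def rotate_annotation(ann: GenomeAnnotation, delta: int) -> GenomeAnnotation:
    """Shift the origin of a circular genome by ``delta`` bp.

    Raises if any feature would be split by the new origin.
    """
    if not ann.circular:
        raise ValueError("rotation only defined for circular genomes")
    L = ann.length
    feats = []
    for f in ann.features:
        s = (f.start - delta) % L
        e = s + (f.end - f.start)
        if e > L:
            raise ValueError(f"rotation splits gene {f.gene_id}")
        feats.append(replace(f, start=s, end=e))
    return GenomeAnnotation(ann.genome_id, L, feats, list(ann.units), circular=True)


# -- I/O ---------------------------------------------------------------


def read_annotation(gff3_path, fasta_path=None) -> GenomeAnnotation:
    """Read a GFF3 gene annotation (plus optional FASTA for the length).

    Genes carrying the same ``operon`` attribute (contiguous, same strand)
    form one transcription unit; genes without one each become their own
    unit.  Genome length comes from the FASTA if given, else from the
    ``##sequence-region`` pragma.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genome_id = None
    length = None
    circular = True
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            genome_id = parts[1]
            length = int(parts[3])
        if d.startswith("circular"):
            circular = d.split()[-1].lower() != "false"
    if fasta_path is not None:
        rec = SeqIO.read(str(fasta_path), "fasta")
        genome_id = rec.id
        length = len(rec.seq)
    if length is None:
        raise ValueError("genome length unavailable: need FASTA or ##sequence-region")

    features: list[GeneFeature] = []
    operon_of: dict[str, str | None] = {}
    order: list[str] = []
    for f in db.all_features(featuretype="gene", order_by="start"):
        gid = f.attributes.get("ID", [f.id])[0]
        kind = f.attributes.get("kind", ["ORF"])[0]
        features.append(GeneFeature(gid, f.start - 1, f.end, f.strand, kind))
        operon_of[gid] = f.attributes.get("operon", [None])[0]
        order.append(gid)

    units: list[TranscriptionUnit] = []
    grouped: dict[str, list[str]] = {}
    for gid in order:
        op = operon_of[gid]
        if op is None:
            units.append(
                TranscriptionUnit(
                    f"TU_{gid}", (gid,), next(f.strand for f in features if f.gene_id == gid)
                )
            )
        else:
            grouped.setdefault(op, []).append(gid)
    strand_of = {f.gene_id: f.strand for f in features}
    for op, genes in grouped.items():
        units.append(TranscriptionUnit(op, tuple(genes), strand_of[genes[0]]))
    return GenomeAnnotation(genome_id or "genome", length, features, units, circular)


def write_annotation(ann: GenomeAnnotation, gff3_path, fasta_path=None, sequence=None) -> None:
    """Write GFF3 (1-based inclusive); optionally the sequence as FASTA."""
    lines = [
        "##gff-version 3",
        f"##sequence-region {ann.genome_id} 1 {ann.length}",
        f"##circular {str(ann.circular).lower()}",
    ]
    unit_of = {g: u.unit_id for u in ann.units for g in u.genes}
    for f in ann.features:
        attrs = f"ID={f.gene_id};operon={unit_of[f.gene_id]};kind={f.kind}"
        lines.append(
            "\t".join(
                [
                    ann.genome_id,
                    "gselex",
                    "gene",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if fasta_path is not None:
        if sequence is None:
            raise ValueError("sequence required to write FASTA")
        with open(fasta_path, "w") as fh:
            fh.write(f">{ann.genome_id}\n")
            for i in range(0, len(sequence), 70):
                fh.write(sequence[i : i + 70] + "\n")


def spacers_to_bed(ann: GenomeAnnotation, spacers: list[IntergenicSpacer], path) -> None:
    """Export spacers as BED6 (0-based half-open); wrapped spacers split in two."""
    lines = ["# BED6: intergenic spacers (name=left/right, score=length)"]
    for sp in spacers:
        name = f"{sp.left_unit}/{sp.right_unit}|{sp.orientation}"
        if sp.wraps:
            segs = [(sp.start, ann.length), (0, sp.end)]
        else:
            segs = [(sp.start, sp.end)]
        for s, e in segs:
            if e > s:
                lines.append(
                    f"{ann.genome_id}\t{s}\t{e}\t{name}\t{sp.length}\t."
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
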