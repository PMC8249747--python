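"""IUPAC degenerate motif search, palindrome test, footprint bookkeeping.

Supports box-motif analysis of protected promoter regions: e.g. locating a
degenerate palindrome such as ATACNNGTAT inside a DNase-I-protected
interval and measuring its offset from the footprint center.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate DNA pattern in IUPAC one-letter code (case-insensitive)."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
        if not self.pattern:
            raise ValueError("empty pattern")

    def __len__(self) -> int:
        return len(self.pattern)


class MotifHit(NamedTuple):
    start: int  # plus-strand coordinate of the match start
    strand: str
    length: int


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def is_revcomp_palindrome(pattern: MotifPattern | str) -> bool:
    """True iff the pattern reads the same as its IUPAC reverse complement
    (ATACNNGTAT is such a palindrome; N is self-complementary)."""
    p = pattern.pattern if isinstance(pattern, MotifPattern) else MotifPattern(pattern).pattern
    return p == revcomp(p)


def _regex(pattern: str) -> re.Pattern:
    # lookahead makes overlapping matches visible
    body = "".join(f"[{IUPAC[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def iupac_search(seq: str, pattern: MotifPattern | str, both_strands: bool = True) -> list[MotifHit]:
    """All (overlapping) match positions of a degenerate pattern.

    Minus-strand hits are matches of the pattern's reverse complement,
    reported at their plus-strand start coordinate.  A self-complementary
    (palindromic) pattern therefore matches each site on both strands.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    hits = [MotifHit(m.start(), "+", len(pattern)) for m in _regex(pattern.pattern).finditer(seq)]
    if both_strands:
        rc = revcomp(pattern.pattern)
        hits += [MotifHit(m.start(), "-", len(pattern)) for m in _regex(rc).finditer(seq)]
    return sorted(hits, key=lambda h: (h.start, h.strand))


@dataclass(frozen=True)
class FootprintInterval:
    """A DNase-I-protected interval with optional hypersensitive positions."""

    start: int
    end: int
    hypersensitive_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("footprint start must be < end")
        for s in self.hypersensitive_sites:
            if not self.start <= s < self.end:
                raise ValueError("hypersensitive site outside footprint")

    @property
    def protected_len(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


class FootprintFlag(NamedTuple):
    hit: MotifHit
    inside: bool
    center_offset: float


def footprint_overlap(fp: FootprintInterval, hits: list[MotifHit]) -> list[FootprintFlag]:
    """For each motif hit: does it lie fully inside the footprint, and how
    far is its center from the footprint center?"""
    flags = []
    for h in hits:
        inside = h.start >= fp.start and h.start + h.length <= fp.end
        offset = (h.start + h.length / 2) - fp.center
        flags.append(FootprintFlag(h, inside, offset))
    return flags


def hits_to_bed(hits: list[MotifHit], path, genome_id="toy_genome", name="motif") -> None:
    with open(path, "w") as fh:
        fh.write("# BED6: IUPAC motif hits\n")
        for h in hits:
            fh.write(f"{genome_id}\t{h.start}\t{h.start + h.length}\t{name}\t0\t{h.strand}\n")
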