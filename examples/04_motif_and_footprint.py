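"""Degenerate palindrome search inside a protected promoter interval.

Plants the ATACnnGTAT box at the center of a synthetic 31-bp protected
region and shows the search, the palindrome test, and the footprint
bookkeeping (the real box spacer bases are unknown; this sequence is
synthetic).
"""

import numpy as np

import gselex as gx
from gselex.motifs import FootprintInterval, footprint_overlap

rng = np.random.default_rng(0)
box = "ATACGGGTAT"  # one concrete realization of ATACNNGTAT
upstream = "".join(rng.choice(list("ACGT"), 110))
downstream = "".join(rng.choice(list("ACGT"), 120))
protected = "".join(rng.choice(list("ACGT"), 10)) + box + "".join(rng.choice(list("ACGT"), 11))
seq = upstream + protected + downstream  # footprint occupies [110, 141)

pattern = gx.MotifPattern("ATACNNGTAT", name="RspR-box-like")
print(f"pattern {pattern.pattern} palindromic: {gx.is_revcomp_palindrome(pattern)}")

hits = gx.iupac_search(seq, pattern)
print(f"hits in {len(seq)} bp: "
      + ", ".join(f"{h.start}{h.strand}" for h in hits))

fp = FootprintInterval(110, 141)
print(f"protected interval: [{fp.start}, {fp.end}) = {fp.protected_len} bp")
for flag in footprint_overlap(fp, hits):
    print(f"  hit at {flag.hit.start}{flag.hit.strand}: inside={flag.inside}, "
          f"offset from footprint center {flag.center_offset:+.1f} bp")
# A palindromic pattern matches each occurrence on both strands at the same
# start; both hits sit fully inside the footprint, centered on it.
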