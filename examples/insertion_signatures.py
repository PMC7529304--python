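"""Classify insertion signatures: templated small insertions and snapbacks.

Small insertions (1-3 bp) are "templated" when the junction word — at least
2 bp of flank, the inserted bases, and at least 2 bp of the other flank —
recurs nearby (within +/-15 nt) with at least 1 nt separating template and
insertion site.  Large insertions (>= 18 nt) carry the "snapback" signature
when they contain a >= 7 nt substring whose reverse complement also occurs
in the insertion, separated by >= 4 nt.
"""

from mmejsig import (GenomeSequence, IndelRecord, classify_small_insertion,
                     classify_snapback_insertion)

# --- templated small insertion ---------------------------------------------
# A single G inserted between ...TAGA and AAAC...; the junction word
# AGA+g+AAA already exists upstream (AGAGAAA), one base away.
left = "GCTTAGAGAAATAGA"
right = "AAACGTCGTCGTCGT"
pad = "CCGG" * 5
genome = GenomeSequence({"chr1": pad + left + right + pad})
pos = len(pad) + len(left)
anchor = genome.base("chr1", pos)
rec = IndelRecord("chr1", pos, anchor, anchor + "G")

match = classify_small_insertion(rec, genome)
print(f"small insertion {rec.event_seq!r}: "
      f"templated={match is not None}")
if match:
    print(f"  template side={match.side} flank_match={match.p2_len}+"
          f"{match.mh2_len} bp, gap={match.template_offset} nt")

# --- snapback large insertion ------------------------------------------------
ins = "ATCGATC" + "TTTT" + "GATCGAT"  # GATCGAT = revcomp(ATCGATC)
rec = IndelRecord("chr1", 2, genome.base("chr1", 2),
                  genome.base("chr1", 2) + ins)
match = classify_snapback_insertion(rec)
print(f"\nlarge insertion {rec.event_seq!r} ({rec.event_len} nt): "
      f"snapback={match is not None}")
if match:
    print(f"  inverted repeat {match.repeat_len} nt, "
          f"separation {match.separation} nt")
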