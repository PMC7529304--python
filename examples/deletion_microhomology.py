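"""Score breakpoint microhomology for individual deletions.

A deletion bears the microhomology signature when the deleted sequence and
the reference sequence immediately 3' of the deletion share a common prefix.
Repair machinery that anneals such repeats removes one copy, so the deleted
segment's start matches what now follows the breakpoint.
"""

from mmejsig import GenomeSequence, IndelRecord, score_deletion

# Reference:        TTG ACG ACGTTAA
# Deleting the first ACG (VCF-style: pos 3, REF=GACG, ALT=G) leaves
# ...TTG | ACGTTAA... — the deleted "ACG" matches the new 3' flank "ACG".
genome = GenomeSequence({"chr1": "TTGACGACGTTAA"})

examples = [
    ("perfect 3 bp repeat", IndelRecord("chr1", 3, "GACG", "G")),
    ("no junction homology", IndelRecord("chr1", 7, "CGTT", "C")),
]

for label, rec in examples:
    scored = score_deletion(rec, genome)
    print(f"{label}: deleted={rec.event_seq!r} len={rec.event_len} "
          f"mh_len={scored.mh_len} class={scored.size_class}")
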