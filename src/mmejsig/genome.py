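"""Reference-genome loading and flank extraction.

All domain-facing coordinates are 1-based inclusive (the VCF convention).
Flank extraction never pads: windows are truncated at contig ends so that
indels near a contig edge remain scorable, with microhomology capped by
the available flank.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO

_VALID = set("ACGTN")
_NONACGTN = re.compile(r"[^ACGTN]")


class GenomeFormatError(ValueError):
    """Raised for malformed or empty reference files."""


@dataclass
class GenomeSequence:
    """Named contigs of upper-case nucleotide sequence (alphabet A,C,G,T,N)."""

    contigs: Dict[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        try:
            return self.contigs[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def length(self, name: str) -> int:
        return len(self[name])

    def base(self, name: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        seq = self[name]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} out of range for contig {name!r} "
                             f"(length {len(seq)})")
        return seq[pos - 1]

    def fetch(self, name: str, start: int, end: int) -> str:
        """Substring covering 1-based inclusive ``[start, end]``, clipped to
        the contig."""
        seq = self[name]
        return seq[max(start - 1, 0):min(end, len(seq))]

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.contigs.items())


def _clean(seq: str) -> str:
    return _NONACGTN.sub("N", seq.upper())


def load_genome(path) -> GenomeSequence:
    """Load a (plain or gzip) FASTA into memory.

    Sequences are upper-cased and any character outside A,C,G,T,N is mapped
    to N. Duplicate contig names and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    contigs: Dict[str, str] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise GenomeFormatError(f"duplicate contig name {rec.id!r} in {path}")
            seq = _clean(str(rec.seq))
            if not seq:
                raise GenomeFormatError(f"empty sequence for contig {rec.id!r} in {path}")
            contigs[rec.id] = seq
    if not contigs:
        raise GenomeFormatError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def write_genome(genome: GenomeSequence, path, width: int = 70) -> None:
    """Write contigs back to FASTA (used by the simulator; round-trips
    through :func:`load_genome`)."""
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def extract_flank(genome: GenomeSequence, contig: str, start: int,
                  length: int, direction: str = "downstream") -> str:
    """Extract up to ``length`` reference bases adjacent to a position.

    ``downstream``: the window starts at ``start`` (inclusive) and runs 3'.
    ``upstream``: the window ends at ``start`` (inclusive) and runs 5'.
    Both are reported 5'->3' on the reference strand and truncated (never
    padded) at contig ends.
    """
    if length <= 0:
        raise ValueError("flank length must be positive")
    seq = genome[contig]
    if not 1 <= start <= len(seq):
        raise IndexError(f"start {start} out of range for contig {contig!r} "
                         f"(length {len(seq)})")
    if direction == "downstream":
        return seq[start - 1:start - 1 + length]
    if direction == "upstream":
        return seq[max(start - length, 0):start]
    raise ValueError(f"direction must be 'downstream' or 'upstream', got {direction!r}")
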