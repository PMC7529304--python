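"""Indel call I/O, quality filtering, and normalization.

Records are held in anchor-base form (the shared leading reference base of
the VCF representation), left-aligned so that junction microhomology shows
up in the downstream flank. Membership throughout the package is by the
normalized key ``(contig, pos, ref, alt)``; genotypes are ignored — presence
of a site in a sample's VCF defines membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pysam

from .genome import GenomeSequence

log = logging.getLogger(__name__)

Key = Tuple[str, int, str, str]

DEFAULT_QUAL_MIN = 40.0


class VariantFormatError(ValueError):
    """Raised for unparseable variant input."""


class ReferenceMismatchError(ValueError):
    """Raised when a record's REF allele disagrees with the genome."""


@dataclass(frozen=True)
class IndelRecord:
    """One insertion or deletion call in anchor-base representation."""

    contig: str
    pos: int  # 1-based position of the anchor base
    ref_allele: str
    alt_allele: str
    qual: Optional[float] = None

    @property
    def kind(self) -> str:
        return "deletion" if len(self.ref_allele) > len(self.alt_allele) else "insertion"

    @property
    def event_seq(self) -> str:
        """The inserted or deleted nucleotides (anchor base excluded)."""
        longer = self.ref_allele if self.kind == "deletion" else self.alt_allele
        return longer[1:]

    @property
    def event_len(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> Key:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


class IndelSet:
    """Ordered collection of IndelRecord keyed by (contig, pos, ref, alt)."""

    def __init__(self, records: Iterable[IndelRecord] = (), sample_label: str = ""):
        self.sample_label = sample_label
        self._records: Dict[Key, IndelRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: IndelRecord) -> None:
        if rec.key in self._records:
            return
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[IndelRecord]:
        return iter(self._records.values())

    def __contains__(self, key: Key) -> bool:
        return key in self._records

    def keys(self):
        return self._records.keys()

    def records(self) -> List[IndelRecord]:
        return list(self._records.values())

    def deletions(self) -> List[IndelRecord]:
        return [r for r in self if r.kind == "deletion"]

    def insertions(self) -> List[IndelRecord]:
        return [r for r in self if r.kind == "insertion"]

    def __repr__(self) -> str:
        return f"IndelSet({self.sample_label!r}, n={len(self)})"


def _is_symbolic(alt: str) -> bool:
    return ("<" in alt or ">" in alt or "[" in alt or "]" in alt
            or alt in {"*", "."} or "." in alt)


def _trim_alleles(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then shared prefix down to a single anchor base."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_indels(path, qual_min: float = DEFAULT_QUAL_MIN,
                sample_label: str = "") -> IndelSet:
    """Read indel calls from a VCF, applying the variant-level quality filter.

    Only indels are kept (allele lengths differ). Multi-allelic rows are
    split into one record per ALT before filtering. Records with QUAL below
    ``qual_min`` — or with QUAL missing, which cannot certify quality — are
    removed. Symbolic alleles and breakends are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    if qual_min < 0:
        raise ValueError("qual_min must be >= 0")
    out = IndelSet(sample_label=sample_label or path.stem)
    n_rows = n_split = n_qual = n_symbolic = n_complex = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VariantFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for row in vf:
            n_rows += 1
            alts = row.alts or ()
            for alt in alts:
                if alt is None or _is_symbolic(alt):
                    n_symbolic += 1
                    continue
                ref = row.ref.upper()
                alt = alt.upper()
                if len(ref) == len(alt):
                    continue  # SNV/MNV
                n_split += 1
                if row.qual is None:
                    n_qual += 1
                    continue
                if row.qual < qual_min:
                    n_qual += 1
                    continue
                pos, ref, alt = _trim_alleles(row.pos, ref, alt)
                if len(ref) > 1 and len(alt) > 1:
                    n_complex += 1
                    continue  # complex substitution, not a simple indel
                if ref[0] != alt[0]:
                    n_complex += 1
                    continue  # un-anchored representation
                out.add(IndelRecord(row.chrom, pos, ref, alt, qual=row.qual))
    log.info("read_indels(%s): rows=%d candidates=%d qual_filtered=%d "
             "symbolic_skipped=%d complex_skipped=%d kept=%d",
             path.name, n_rows, n_split, n_qual, n_symbolic, n_complex, len(out))
    return out


def normalize_indel(record: IndelRecord, genome: GenomeSequence) -> IndelRecord:
    """Left-align an indel and reduce it to anchor-base-minimal form.

    The event is shifted left while the last base of the event sequence
    equals the reference base at the current anchor position; this is
    idempotent and canonicalizes equivalent representations of the same
    indel onto the leftmost one.
    """
    pos, ref, alt = _trim_alleles(record.pos, record.ref_allele, record.alt_allele)
    if len(ref) > 1 and len(alt) > 1:
        raise VariantFormatError(f"not a simple indel: {record}")
    expected = genome.fetch(record.contig, record.pos, record.pos + len(record.ref_allele) - 1)
    if expected != record.ref_allele:
        raise ReferenceMismatchError(
            f"REF {record.ref_allele!r} at {record.contig}:{record.pos} does not "
            f"match reference {expected!r}")
    kind = "deletion" if len(ref) > len(alt) else "insertion"
    seq = (ref if kind == "deletion" else alt)[1:]
    while pos > 1 and genome.base(record.contig, pos) == seq[-1]:
        seq = genome.base(record.contig, pos) + seq[:-1]
        pos -= 1
    anchor = genome.base(record.contig, pos)
    if kind == "deletion":
        ref2, alt2 = anchor + seq, anchor
    else:
        ref2, alt2 = anchor, anchor + seq
    return replace(record, pos=pos, ref_allele=ref2, alt_allele=alt2)


def normalize_set(records: IndelSet, genome: GenomeSequence) -> IndelSet:
    """Normalize every record in a set, dropping reference-inconsistent ones
    with a logged count."""
    out = IndelSet(sample_label=records.sample_label)
    n_bad = 0
    for rec in records:
        try:
            out.add(normalize_indel(rec, genome))
        except (ReferenceMismatchError, VariantFormatError, KeyError, IndexError) as exc:
            n_bad += 1
            log.debug("dropping record %s: %s", rec, exc)
    if n_bad:
        log.warning("normalize_set(%s): dropped %d reference-inconsistent records",
                    records.sample_label, n_bad)
    return out


def exclude_known(target: IndelSet, exclusions: Iterable[IndelSet],
                  by_position: bool = False) -> IndelSet:
    """Remove records whose key appears in any exclusion set (known-variant
    databases, supplied as VCFs). Order of the remainder is preserved.

    With ``by_position`` the match ignores alleles and uses (contig, pos)
    only; the default is the exact normalized key.
    """
    if by_position:
        known = {(r.contig, r.pos) for ex in exclusions for r in ex}
        keep = [r for r in target if (r.contig, r.pos) not in known]
    else:
        known = {k for ex in exclusions for k in ex.keys()}
        keep = [r for r in target if r.key not in known]
    out = IndelSet(keep, sample_label=target.sample_label)
    log.info("exclude_known(%s): removed %d of %d", target.sample_label,
             len(target) - len(out), len(target))
    return out
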