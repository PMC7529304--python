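"""Junction-microhomology scoring of deletions and threshold tables.

A deletion repaired by microhomology-mediated end joining leaves a short
identical sequence shared by the deleted segment and the retained sequence
just 3' of it. With left-aligned calls, that homology appears as a common
prefix of the deleted sequence and the downstream reference flank, so the
score is the length of their longest common prefix ("contiguous matching
nucleotides counted from the beginning of each sequence"), capped at 20 bp
because no analysis threshold above 20 is used.

Deletions are analysed in two size classes — small (2-29 bp) and long
(30-500 bp) — and stratified over minimum-mh thresholds T = 2..20. At each
T, deletions shorter than T are excluded (they cannot possibly carry a
T bp match), the remainder are split by mh >= T, and the pre-existing vs
new proportions are compared with a two-proportion chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import PartitionResult
from .genome import GenomeSequence, extract_flank
from .stats import ContingencyTable, format_p, proportion_chisq
from .variants import IndelRecord

log = logging.getLogger(__name__)

MH_CAP = 20
SMALL_BOUNDS = (2, 29)
LONG_BOUNDS = (30, 500)
DEFAULT_THRESHOLDS = tuple(range(2, 21))

TABLE_COLUMNS = ["minimum_mh", "pre_existing_deletions", "pre_with_mh",
                 "pre_fraction", "new_deletions", "new_with_mh",
                 "new_fraction", "p", "p_raw"]


@dataclass(frozen=True)
class DeletionMH:
    """A scored deletion: its microhomology length and size class."""

    record: IndelRecord
    mh_len: int
    size_class: str  # "small" or "long"


@dataclass(frozen=True)
class ThresholdRow:
    """One threshold-stratified row of counts, fractions and the test p."""

    T: int
    n_pre: int
    mh_pre: int
    frac_pre: float
    n_new: int
    mh_new: int
    frac_new: float
    p_value: float  # nan when undefined
    label: str      # display form: numeric, "NS", or "NA"


def size_class_of(event_len: int) -> Optional[str]:
    if SMALL_BOUNDS[0] <= event_len <= SMALL_BOUNDS[1]:
        return "small"
    if LONG_BOUNDS[0] <= event_len <= LONG_BOUNDS[1]:
        return "long"
    return None


def microhomology_length(deletion_seq: str, adjacent_seq: str,
                         cap: int = MH_CAP) -> int:
    """Longest common prefix of the deleted sequence and its 3' flank.

    N is ambiguous and never matches any base (including another N), so
    homology cannot run through masked or unknown reference. The result is
    capped at ``cap``.
    """
    if not deletion_seq:
        raise ValueError("deletion_seq must be non-empty")
    k = 0
    limit = min(len(deletion_seq), len(adjacent_seq), cap)
    while k < limit and deletion_seq[k] == adjacent_seq[k] and deletion_seq[k] != "N":
        k += 1
    return k


def score_deletion(record: IndelRecord, genome: GenomeSequence,
                   also_upstream: bool = False) -> DeletionMH:
    """Score one deletion for junction microhomology.

    The adjacent sequence is the downstream (3') reference flank beginning
    at the first base after the deleted interval; its window is
    ``min(event_len, 20)`` bp since the score can exceed neither. With
    ``also_upstream`` the score is the maximum of the 3'-prefix match and
    the corresponding 5'-suffix match (non-default variant).
    """
    if record.kind != "deletion":
        raise ValueError(f"not a deletion: {record}")
    cls = size_class_of(record.event_len)
    if cls is None:
        raise ValueError(f"deletion length {record.event_len} outside 2-500 bp: "
                         f"{record.contig}:{record.pos}")
    del_seq = record.event_seq
    window = min(record.event_len, MH_CAP)
    # deleted interval is [pos+1, pos+event_len]; flank starts just after it
    flank_start = record.pos + record.event_len + 1
    contig_len = genome.length(record.contig)
    if flank_start > contig_len:
        downstream = ""
    else:
        downstream = extract_flank(genome, record.contig, flank_start, window,
                                   "downstream")
    mh = microhomology_length(del_seq, downstream)
    if also_upstream and record.pos >= 1:
        upstream = extract_flank(genome, record.contig, record.pos, window,
                                 "upstream")
        mh = max(mh, microhomology_length(del_seq[::-1], upstream[::-1]))
    return DeletionMH(record=record, mh_len=mh, size_class=cls)


def score_deletions(records: Iterable[IndelRecord], genome: GenomeSequence,
                    also_upstream: bool = False) -> List[DeletionMH]:
    """Score all in-range deletions; out-of-range lengths are logged and
    skipped, not scored."""
    out = []
    n_rejected = 0
    for rec in records:
        if rec.kind != "deletion":
            continue
        if size_class_of(rec.event_len) is None:
            n_rejected += 1
            log.debug("deletion length %d outside 2-500 bp, not scored: %s:%d",
                      rec.event_len, rec.contig, rec.pos)
            continue
        out.append(score_deletion(rec, genome, also_upstream=also_upstream))
    if n_rejected:
        log.info("score_deletions: %d deletions outside 2-500 bp not scored",
                 n_rejected)
    return out


def _threshold_row(pre: Sequence[DeletionMH], new: Sequence[DeletionMH],
                   T: int, continuity_correction: bool,
                   ns_alpha: float) -> ThresholdRow:
    pre_considered = [d for d in pre if d.record.event_len >= T]
    new_considered = [d for d in new if d.record.event_len >= T]
    n_pre, n_new = len(pre_considered), len(new_considered)
    mh_pre = sum(1 for d in pre_considered if d.mh_len >= T)
    mh_new = sum(1 for d in new_considered if d.mh_len >= T)
    if n_pre == 0 or n_new == 0:
        p, label = float("nan"), "NA"
    else:
        _, p = proportion_chisq(ContingencyTable(mh_pre, n_pre, mh_new, n_new),
                                continuity_correction=continuity_correction)
        label = format_p(p, ns_alpha=ns_alpha)
    return ThresholdRow(
        T=T, n_pre=n_pre, mh_pre=mh_pre,
        frac_pre=(mh_pre / n_pre if n_pre else 0.0),
        n_new=n_new, mh_new=mh_new,
        frac_new=(mh_new / n_new if n_new else 0.0),
        p_value=p, label=label)


def build_deletion_table(partition: PartitionResult, genome: GenomeSequence,
                         size_class: str,
                         thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
                         continuity_correction: bool = True,
                         ns_alpha: float = 0.05,
                         also_upstream: bool = False) -> List[ThresholdRow]:
    """Build the threshold-stratified deletion report for one size class."""
    if size_class not in ("small", "long"):
        raise ValueError("size_class must be 'small' or 'long'")
    pre = [d for d in score_deletions(partition.preexisting.deletions(), genome,
                                      also_upstream=also_upstream)
           if d.size_class == size_class]
    new = [d for d in score_deletions(partition.new.deletions(), genome,
                                      also_upstream=also_upstream)
           if d.size_class == size_class]
    rows = [_threshold_row(pre, new, T, continuity_correction, ns_alpha)
            for T in thresholds]
    _assert_monotone(rows)
    return rows


def _assert_monotone(rows: List[ThresholdRow]) -> None:
    # considered and matching counts can only shrink as T grows
    for a, b in zip(rows, rows[1:]):
        if b.T <= a.T:
            continue
        if b.n_pre > a.n_pre or b.n_new > a.n_new \
                or b.mh_pre > a.mh_pre or b.mh_new > a.mh_new:
            raise AssertionError(f"threshold table not monotone between T={a.T} "
                                 f"and T={b.T}")


def table_to_dataframe(rows: Sequence[ThresholdRow]) -> pd.DataFrame:
    """Display form: fractions rounded to 2 decimals, p rendered under the
    report style, raw p retained in a machine-readable column."""
    data = [{
        "minimum_mh": r.T,
        "pre_existing_deletions": r.n_pre,
        "pre_with_mh": r.mh_pre,
        "pre_fraction": round(r.frac_pre, 2),
        "new_deletions": r.n_new,
        "new_with_mh": r.mh_new,
        "new_fraction": round(r.frac_new, 2),
        "p": r.label,
        "p_raw": r.p_value,
    } for r in rows]
    return pd.DataFrame(data, columns=TABLE_COLUMNS)
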