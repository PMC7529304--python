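"""Classification of insertions bearing synthesis-dependent MMEJ signatures.

Two mechanisms leave recognisable footprints:

* **Templated small insertions (trans).** A 1-3 bp insertion produced by
  transient mispriming on a nearby template. The junction word — at least
  2 bp of flank on each side plus the inserted bases (symbols P2 and mh2;
  their template counterparts P1 and mh1) — recurs elsewhere within the
  +/-15 nt reference context, separated from the junction flanks by a gap
  of at least 1 nt.

* **Snapback large insertions (cis).** An insertion synthesised by a
  strand folding back on itself carries an inverted repeat: a substring of
  >= 7 nt whose reverse complement also occurs in the insertion, with the
  two footprints separated by >= 4 nt. Only insertions of at least
  2*7 + 4 = 18 nt are evaluated, since shorter ones cannot satisfy the rule
  and would be spurious negatives.

Insertions of 4-17 bp belong to neither analysis; builders count them in a
logged "unclassified" bucket so every insertion lands in exactly one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .cohort import PartitionResult
from .genome import GenomeSequence, extract_flank
from .stats import ContingencyTable, format_p, proportion_chisq
from .variants import IndelRecord

log = logging.getLogger(__name__)

SMALL_INS_MAX = 3
CONTEXT_WINDOW = 15
MIN_FLANK_MATCH = 2
MIN_TEMPLATE_GAP = 1

MIN_REPEAT = 7
MIN_SEPARATION = 4
SNAPBACK_MIN_LEN = 2 * MIN_REPEAT + MIN_SEPARATION  # 18

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class IneligibleInsertionError(ValueError):
    """Raised when an insertion's length puts it outside an analysis."""


def reverse_complement(seq: str) -> str:
    """Strict A<->T, C<->G reverse complement; N or other ambiguity codes
    are not complemented and never match anything downstream."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallInsertionMatch:
    """A template copy of flank+insertion+flank found near the junction."""

    side: str            # "upstream" or "downstream" of the insertion point
    p2_len: int          # flank match 5' of the insertion (>= 2)
    mh2_len: int         # flank match 3' of the insertion (>= 2)
    template_offset: int  # gap between template copy and junction flanks (>= 1)

    @property
    def match_len(self) -> int:
        return self.p2_len + self.mh2_len


@dataclass(frozen=True)
class SnapbackMatch:
    """An inverted repeat inside the insertion sequence."""

    repeat_len: int
    first_start: int   # 0-offset within the insertion
    second_start: int
    separation: int    # gap between end of first copy and start of second


def classify_small_insertion(record: IndelRecord, genome: GenomeSequence,
                             context: int = CONTEXT_WINDOW
                             ) -> Optional[SmallInsertionMatch]:
    """Test a 1-3 bp insertion for a nearby template copy.

    Let L be up to ``context`` nt of reference immediately 5' of the
    insertion point and R up to ``context`` nt immediately 3'. The call is
    positive iff for some k >= 2, m >= 2 the word suffix_k(L) + insertion +
    prefix_m(R) occurs within L+R with its footprint separated by >= 1 nt
    from the junction bases contributing those flanks. The reported match
    maximises k+m; ties prefer the upstream side, then the smallest gap.

    Returns None for a negative; raises for insertions longer than 3 bp.
    """
    if record.kind != "insertion":
        raise ValueError(f"not an insertion: {record}")
    if record.event_len > SMALL_INS_MAX:
        raise IneligibleInsertionError(
            f"insertion of {record.event_len} bp exceeds the {SMALL_INS_MAX} bp "
            f"small-insertion cap: {record.contig}:{record.pos}")
    ins = record.event_seq
    contig_len = genome.length(record.contig)
    left = extract_flank(genome, record.contig, record.pos, context, "upstream")
    if record.pos + 1 > contig_len:
        right = ""
    else:
        right = extract_flank(genome, record.contig, record.pos + 1, context,
                              "downstream")
    if len(left) < MIN_FLANK_MATCH or len(right) < MIN_FLANK_MATCH:
        return None  # contig edge: flank minimums cannot be satisfied
    ctx = left + right
    nl = len(left)
    best: Optional[Tuple[int, int, int, SmallInsertionMatch]] = None
    for k in range(MIN_FLANK_MATCH, nl + 1):
        for m in range(MIN_FLANK_MATCH, len(right) + 1):
            word = left[nl - k:] + ins + right[:m]
            if "N" in word:
                continue  # N never matches
            w = len(word)
            junction_start = nl - k          # footprint of the junction flanks
            junction_end = nl + m            # exclusive, within ctx
            start = 0
            while True:
                s = ctx.find(word, start)
                if s == -1:
                    break
                start = s + 1
                if s + w <= junction_start - MIN_TEMPLATE_GAP:
                    gap = junction_start - (s + w)
                    side = "upstream"
                elif s >= junction_end + MIN_TEMPLATE_GAP:
                    gap = s - junction_end
                    side = "downstream"
                else:
                    continue
                cand = SmallInsertionMatch(side=side, p2_len=k, mh2_len=m,
                                           template_offset=gap)
                rank = (k + m, 0 if side == "upstream" else 1, gap)
                if best is None or (rank[0], -rank[1], -rank[2]) > \
                        (best[0], -best[1], -best[2]):
                    best = (rank[0], rank[1], rank[2], cand)
    return best[3] if best else None


def classify_snapback_insertion(record: IndelRecord,
                                min_repeat: int = MIN_REPEAT,
                                min_separation: int = MIN_SEPARATION
                                ) -> Optional[SnapbackMatch]:
    """Test a large insertion for an internal inverted repeat.

    Positive iff some substring of length >= ``min_repeat`` has its reverse
    complement also present, the two non-overlapping footprints separated by
    at least ``min_separation`` nt. The reported match maximises repeat
    length, with ties broken by the smallest first_start then second_start.
    Insertions shorter than 2*min_repeat + min_separation are rejected, not
    evaluated.
    """
    if record.kind != "insertion":
        raise ValueError(f"not an insertion: {record}")
    seq = record.event_seq
    min_len = 2 * min_repeat + min_separation
    if len(seq) < min_len:
        raise IneligibleInsertionError(
            f"insertion of {len(seq)} bp below the {min_len} bp snapback "
            f"minimum: {record.contig}:{record.pos}")
    n = len(seq)
    for rep in range((n - min_separation) // 2, min_repeat - 1, -1):
        for i in range(0, n - (2 * rep + min_separation) + 1):
            first = seq[i:i + rep]
            if "N" in first:
                continue
            target = reverse_complement(first)
            if "N" in target:
                continue
            j = seq.find(target, i + rep + min_separation)
            if j != -1:
                return SnapbackMatch(repeat_len=rep, first_start=i,
                                     second_start=j, separation=j - (i + rep))
    return None


@dataclass(frozen=True)
class InsertionSummary:
    """Counts and mean lengths for one insertion analysis (small or snapback)."""

    analysis: str  # "small" or "snapback"
    n_pre: int
    pos_pre: int
    n_new: int
    pos_new: int
    p_value: float
    p_label: str
    mean_len_pre: float
    mean_len_new: float


@dataclass(frozen=True)
class InsertionCall:
    """Per-insertion classification record."""

    record: IndelRecord
    bucket: str            # "small", "snapback", or "unclassified"
    positive: Optional[bool]
    match: Optional[object]


def classify_insertions(records: Iterable[IndelRecord], genome: GenomeSequence,
                        context: int = CONTEXT_WINDOW,
                        min_repeat: int = MIN_REPEAT,
                        min_separation: int = MIN_SEPARATION
                        ) -> List[InsertionCall]:
    """Route every insertion to exactly one bucket and classify it."""
    snap_min = 2 * min_repeat + min_separation
    calls = []
    n_unclassified = 0
    for rec in records:
        if rec.kind != "insertion":
            continue
        if rec.event_len <= SMALL_INS_MAX:
            m = classify_small_insertion(rec, genome, context=context)
            calls.append(InsertionCall(rec, "small", m is not None, m))
        elif rec.event_len >= snap_min:
            m = classify_snapback_insertion(rec, min_repeat=min_repeat,
                                            min_separation=min_separation)
            calls.append(InsertionCall(rec, "snapback", m is not None, m))
        else:
            n_unclassified += 1
            calls.append(InsertionCall(rec, "unclassified", None, None))
    if n_unclassified:
        log.info("classify_insertions: %d insertions of 4-%d bp in neither "
                 "analysis (unclassified bucket)", n_unclassified, snap_min - 1)
    return calls


def _summary(analysis: str, pre: Sequence[InsertionCall],
             new: Sequence[InsertionCall], continuity_correction: bool,
             ns_alpha: float) -> InsertionSummary:
    n_pre, n_new = len(pre), len(new)
    pos_pre = sum(1 for c in pre if c.positive)
    pos_new = sum(1 for c in new if c.positive)
    if n_pre == 0 or n_new == 0:
        p, label = float("nan"), "NA"
    else:
        _, p = proportion_chisq(ContingencyTable(pos_pre, n_pre, pos_new, n_new),
                                continuity_correction=continuity_correction)
        label = format_p(p, ns_alpha=ns_alpha)
    mean_pre = (sum(c.record.event_len for c in pre) / n_pre) if n_pre else 0.0
    mean_new = (sum(c.record.event_len for c in new) / n_new) if n_new else 0.0
    return InsertionSummary(analysis=analysis, n_pre=n_pre, pos_pre=pos_pre,
                            n_new=n_new, pos_new=pos_new, p_value=p,
                            p_label=label, mean_len_pre=mean_pre,
                            mean_len_new=mean_new)


def build_insertion_tables(partition: PartitionResult, genome: GenomeSequence,
                           context: int = CONTEXT_WINDOW,
                           min_repeat: int = MIN_REPEAT,
                           min_separation: int = MIN_SEPARATION,
                           continuity_correction: bool = True,
                           ns_alpha: float = 0.05
                           ) -> Tuple[InsertionSummary, InsertionSummary,
                                      List[InsertionCall], List[InsertionCall]]:
    """Small-insertion and snapback summaries for one pre/new partition.

    Returns (small_summary, snapback_summary, pre_calls, new_calls).
    """
    kw = dict(context=context, min_repeat=min_repeat,
              min_separation=min_separation)
    pre_calls = classify_insertions(partition.preexisting.insertions(), genome, **kw)
    new_calls = classify_insertions(partition.new.insertions(), genome, **kw)
    small = _summary("small",
                     [c for c in pre_calls if c.bucket == "small"],
                     [c for c in new_calls if c.bucket == "small"],
                     continuity_correction, ns_alpha)
    snap = _summary("snapback",
                    [c for c in pre_calls if c.bucket == "snapback"],
                    [c for c in new_calls if c.bucket == "snapback"],
                    continuity_correction, ns_alpha)
    return small, snap, pre_calls, new_calls
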