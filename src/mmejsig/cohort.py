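"""Cohort set algebra: spurious-call removal and pre/new partitioning.

Each subject contributes a pair of call sets: primary B cells sampled
before transformation and the lymphoblastoid cell line (LCL) derived from
them. Indels shared between different subjects are assumed spurious
(artifacts of calling against a common reference) and removed everywhere.
Each subject's LCL calls are then partitioned into the pre-existing set
(present in both samples, i.e. arose at the B-cell stage) and the new set
(unique to the LCL, i.e. arose after transformation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from .variants import IndelSet, Key

log = logging.getLogger(__name__)


@dataclass
class SubjectCalls:
    label: str
    bcell: IndelSet
    lcl: IndelSet


@dataclass
class PartitionResult:
    """Pre-existing (B-cell ∩ LCL) and new (LCL-unique) sets for one subject."""

    preexisting: IndelSet
    new: IndelSet
    subject_label: str = ""


def remove_cross_subject_shared(subjects: Sequence[SubjectCalls]) -> List[SubjectCalls]:
    """Drop any indel key seen in two or more subjects from all sets.

    With a single subject the rule cannot apply; the input is returned
    unchanged with a warning.
    """
    if len(subjects) < 2:
        log.warning("remove_cross_subject_shared: only %d subject(s); "
                    "cross-subject filter not applied", len(subjects))
        return list(subjects)
    seen_in: Dict[Key, Set[int]] = {}
    for i, subj in enumerate(subjects):
        for s in (subj.bcell, subj.lcl):
            for key in s.keys():
                seen_in.setdefault(key, set()).add(i)
    spurious = {k for k, owners in seen_in.items() if len(owners) >= 2}
    out = []
    for subj in subjects:
        bc = IndelSet((r for r in subj.bcell if r.key not in spurious),
                      sample_label=subj.bcell.sample_label)
        lc = IndelSet((r for r in subj.lcl if r.key not in spurious),
                      sample_label=subj.lcl.sample_label)
        out.append(SubjectCalls(subj.label, bc, lc))
    log.info("remove_cross_subject_shared: removed %d shared keys across %d subjects",
             len(spurious), len(subjects))
    return out


def partition_pre_new(bcell: IndelSet, lcl: IndelSet,
                      subject_label: str = "") -> PartitionResult:
    """Split the LCL set into pre-existing (∩ B-cell) and new (LCL-unique).

    B-cell-unique calls are discarded from the analysis (they cannot be
    post-transformation events); their count is logged for transparency.
    """
    bkeys = set(bcell.keys())
    pre = IndelSet((r for r in lcl if r.key in bkeys), sample_label="preexisting")
    new = IndelSet((r for r in lcl if r.key not in bkeys), sample_label="new")
    n_bcell_only = len(bcell) - len(pre)
    log.info("partition_pre_new(%s): preexisting=%d new=%d bcell_only_discarded=%d",
             subject_label, len(pre), len(new), n_bcell_only)
    return PartitionResult(preexisting=pre, new=new, subject_label=subject_label)
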