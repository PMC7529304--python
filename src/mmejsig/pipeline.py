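"""End-to-end orchestration: filter -> exclude -> clean -> partition ->
score -> test, with deterministic TSV/JSON outputs per subject."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .cohort import PartitionResult, SubjectCalls, partition_pre_new, \
    remove_cross_subject_shared
from .deletions import build_deletion_table, table_to_dataframe, ThresholdRow
from .genome import load_genome
from .insertions import InsertionCall, InsertionSummary, build_insertion_tables
from .variants import DEFAULT_QUAL_MIN, exclude_known, normalize_set, read_indels

log = logging.getLogger(__name__)


@dataclass
class SubjectInput:
    label: str
    bcell_vcf: str
    lcl_vcf: str


@dataclass
class RunConfig:
    """All fixed constants of the analysis, overridable per run."""

    reference: str = ""
    subjects: List[SubjectInput] = field(default_factory=list)
    exclusion_vcfs: List[str] = field(default_factory=list)
    qual_min: float = DEFAULT_QUAL_MIN
    thresholds: Tuple[int, ...] = tuple(range(2, 21))
    small_del_bounds: Tuple[int, int] = (2, 29)
    long_del_bounds: Tuple[int, int] = (30, 500)
    small_ins_max: int = 3
    min_repeat: int = 7
    min_separation: int = 4
    context_window: int = 15
    continuity_correction: bool = True
    ns_alpha: float = 0.05
    exclusion_by_position: bool = False
    output_dir: str = "mmejsig_out"

    @property
    def snapback_min(self) -> int:
        return 2 * self.min_repeat + self.min_separation

    def validate(self) -> None:
        if self.small_del_bounds[1] + 1 != self.long_del_bounds[0]:
            raise ValueError("deletion size classes must be contiguous")
        if self.snapback_min < 2 * self.min_repeat + self.min_separation:
            raise ValueError("snapback minimum inconsistent with repeat/"
                             "separation minimums")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        subjects = [SubjectInput(**s) for s in raw.pop("subjects", [])]
        cfg = cls(subjects=subjects, **raw)
        cfg.validate()
        return cfg

    def echo(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SubjectResult:
    label: str
    partition: PartitionResult
    small_table: List[ThresholdRow]
    long_table: List[ThresholdRow]
    small_ins: InsertionSummary
    snapback_ins: InsertionSummary
    pre_calls: List[InsertionCall]
    new_calls: List[InsertionCall]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _summary_df(small: InsertionSummary, snap: InsertionSummary):
    import pandas as pd
    rows = []
    for s in (small, snap):
        rows.append({"analysis": s.analysis, "pre_insertions": s.n_pre,
                     "pre_positive": s.pos_pre, "new_insertions": s.n_new,
                     "new_positive": s.pos_new, "p": s.p_label,
                     "p_raw": s.p_value,
                     "mean_len_pre": round(s.mean_len_pre, 2),
                     "mean_len_new": round(s.mean_len_new, 2)})
    return pd.DataFrame(rows)


def _calls_df(calls: Sequence[InsertionCall], origin: str):
    import pandas as pd
    rows = []
    for c in calls:
        r = c.record
        rows.append({"set": origin, "contig": r.contig, "pos": r.pos,
                     "ref": r.ref_allele, "alt": r.alt_allele,
                     "length": r.event_len, "bucket": c.bucket,
                     "positive": ("" if c.positive is None else str(c.positive)),
                     "match": ("" if c.match is None else repr(c.match))})
    return pd.DataFrame(rows, columns=["set", "contig", "pos", "ref", "alt",
                                       "length", "bucket", "positive", "match"])


def run_full_analysis(config: RunConfig) -> List[SubjectResult]:
    """Run the whole pipeline and write per-subject reports.

    Stages: read + QUAL-filter indels, normalize, remove known variants,
    remove cross-subject shared calls, partition into pre-existing vs new,
    build deletion threshold tables (both size classes) and insertion
    summaries, and emit TSVs plus a run manifest.
    """
    config.validate()
    if not config.subjects:
        raise ValueError("no subjects configured")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(config.reference)
    exclusions = [normalize_set(read_indels(p, qual_min=0.0), genome)
                  for p in config.exclusion_vcfs]

    cleaned_subjects: List[SubjectCalls] = []
    checksums: Dict[str, str] = {config.reference: _sha256(config.reference)}
    for subj in config.subjects:
        for p in (subj.bcell_vcf, subj.lcl_vcf):
            if not Path(p).exists():
                raise FileNotFoundError(
                    f"subject {subj.label}: missing VCF {p}")
            checksums[p] = _sha256(p)
        bcell = normalize_set(read_indels(subj.bcell_vcf, config.qual_min,
                                          f"{subj.label}_bcell"), genome)
        lcl = normalize_set(read_indels(subj.lcl_vcf, config.qual_min,
                                        f"{subj.label}_lcl"), genome)
        if exclusions:
            bcell = exclude_known(bcell, exclusions,
                                  by_position=config.exclusion_by_position)
            lcl = exclude_known(lcl, exclusions,
                                by_position=config.exclusion_by_position)
        cleaned_subjects.append(SubjectCalls(subj.label, bcell, lcl))

    cleaned_subjects = remove_cross_subject_shared(cleaned_subjects)

    results = []
    partition_summary = []
    for subj in cleaned_subjects:
        part = partition_pre_new(subj.bcell, subj.lcl, subject_label=subj.label)
        small_table = build_deletion_table(
            part, genome, "small", thresholds=config.thresholds,
            continuity_correction=config.continuity_correction,
            ns_alpha=config.ns_alpha)
        long_table = build_deletion_table(
            part, genome, "long", thresholds=config.thresholds,
            continuity_correction=config.continuity_correction,
            ns_alpha=config.ns_alpha)
        small_ins, snap_ins, pre_calls, new_calls = build_insertion_tables(
            part, genome, context=config.context_window,
            min_repeat=config.min_repeat, min_separation=config.min_separation,
            continuity_correction=config.continuity_correction,
            ns_alpha=config.ns_alpha)
        res = SubjectResult(subj.label, part, small_table, long_table,
                            small_ins, snap_ins, pre_calls, new_calls)
        results.append(res)
        partition_summary.append({"subject": subj.label,
                                  "preexisting": len(part.preexisting),
                                  "new": len(part.new),
                                  "lcl_total": len(subj.lcl)})

        table_to_dataframe(small_table).to_csv(
            outdir / f"{subj.label}_small_deletions.tsv", sep="\t", index=False)
        table_to_dataframe(long_table).to_csv(
            outdir / f"{subj.label}_long_deletions.tsv", sep="\t", index=False)
        _summary_df(small_ins, snap_ins).to_csv(
            outdir / f"{subj.label}_insertion_summary.tsv", sep="\t", index=False)
        import pandas as pd
        pd.concat([_calls_df(pre_calls, "preexisting"),
                   _calls_df(new_calls, "new")], ignore_index=True).to_csv(
            outdir / f"{subj.label}_insertion_calls.tsv", sep="\t", index=False)

    import pandas as pd
    pd.DataFrame(partition_summary).to_csv(outdir / "partition_summary.tsv",
                                           sep="\t", index=False)
    manifest = {"package": "mmejsig", "version": __version__,
                "config": config.echo(), "input_checksums": checksums}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("run_full_analysis: wrote reports for %d subject(s) to %s",
             len(results), outdir)
    return results
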