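"""Synthetic reference and paired indel call sets with planted signatures.

The generator emulates the study design: for each subject, a "B-cell" call
set and an "LCL" call set that share a pre-existing subset, with new events
appearing only in the LCL set. Planted event classes:

* ``mh_deletion`` — a deletion whose 3' flank is written so that its common
  prefix with the deleted sequence has exactly the planted length (drawn
  from a configurable distribution over 2..20);
* ``plain_deletion`` — a deletion with a forced first-base flank mismatch
  (microhomology exactly 0), so truth labels are exact by construction;
* ``templated_small_ins`` — a 1-3 bp insertion with a template copy of
  flank(>=2) + insertion + flank(>=2) written into the upstream context at
  a gap >= 1 nt;
* ``plain_small_ins`` / ``plain_large_ins`` — rejection-resampled until the
  corresponding classifier calls them negative;
* ``snapback_ins`` — an insertion built as repeat + spacer + reverse
  complement of the repeat (plus optional tail), length >= 18 nt.

Events are placed on a fixed slot grid (one event per slot, slots shuffled
by the seeded generator) so footprints can never collide, and keep a 50 bp
margin from contig ends so flank extraction is never truncated. Every
planted record is its own left-aligned normal form (the base preceding the
event is forced to mismatch the event's last base), so pipeline
normalization is the identity on the planted representation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import SubjectCalls
from .genome import GenomeSequence
from .insertions import (SMALL_INS_MAX, classify_small_insertion,
                         classify_snapback_insertion, reverse_complement)
from .variants import IndelRecord, IndelSet

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
EDGE_MARGIN = 50


@dataclass
class SimulationConfig:
    """Study-condition knobs for the simulator.

    Default counts are scaled-down versions of the reported cohort (two
    subjects; small-deletion mh fractions 0.77 pre vs 0.84 new; long
    deletions in similar proportion; small-insertion signature fraction
    equal between sets, snapback fraction enriched in the new set).
    """

    genome_length: int = 400_000   # bp per contig
    n_contigs: int = 2
    gc_content: float = 0.41       # human-like background

    n_pre_small_del: int = 400
    n_new_small_del: int = 330
    n_pre_long_del: int = 45
    n_new_long_del: int = 48
    mh_fraction_pre: float = 0.77
    mh_fraction_new: float = 0.84
    # weights over designated mh lengths 2..20; default geometric decay
    mh_length_distribution: Optional[Sequence[float]] = None

    n_small_ins_pre: int = 120
    n_small_ins_new: int = 120
    templated_fraction_pre: float = 0.10
    templated_fraction_new: float = 0.10

    n_large_ins_pre: int = 40
    n_large_ins_new: int = 60
    snapback_fraction_pre: float = 0.25
    snapback_fraction_new: float = 0.45

    n_bcell_unique: int = 20        # B-cell-only noise events (discarded downstream)
    plain_mh_policy: str = "zero"   # "zero": force mh 0; "random": leave flank random
    seed: int = 0

    def mh_weights(self) -> np.ndarray:
        if self.mh_length_distribution is not None:
            w = np.asarray(self.mh_length_distribution, dtype=float)
            if len(w) != 19 or (w < 0).any() or w.sum() <= 0:
                raise ValueError("mh_length_distribution must be 19 non-negative "
                                 "weights over lengths 2..20")
        else:
            w = 0.75 ** np.arange(19, dtype=float)
        return w / w.sum()


@dataclass
class TruthEntry:
    key: Tuple[str, int, str, str]
    event_class: str
    set_assignment: str  # "preexisting", "new", or "bcell_only"
    params: Dict = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    entries: List[TruthEntry] = field(default_factory=list)

    def by_key(self) -> Dict[Tuple[str, int, str, str], TruthEntry]:
        return {tuple(e.key): e for e in self.entries}

    def of_class(self, *classes: str) -> List[TruthEntry]:
        return [e for e in self.entries if e.event_class in classes]

    def to_json(self, path) -> None:
        with open(path, "w") as out:
            json.dump([asdict(e) for e in self.entries], out, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls([TruthEntry(key=tuple(e["key"]), event_class=e["event_class"],
                               set_assignment=e["set_assignment"],
                               params=e.get("params", {})) for e in raw])


def simulate_reference(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> GenomeSequence:
    """I.i.d. background sequence at the configured GC content."""
    if not 0.0 <= config.gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = rng or np.random.default_rng(config.seed)
    at, gc = (1 - config.gc_content) / 2, config.gc_content / 2
    contigs = {}
    for i in range(config.n_contigs):
        draw = rng.choice(_BASES, size=config.genome_length,
                          p=[at, gc, gc, at])
        contigs[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeSequence(contigs)


SMALL_SLOT = 110   # fits anchor offset + 29 bp deletion + 21 bp flank, or any insertion context
LONG_SLOT = 580    # fits a 500 bp deletion + flank


class _SlotAllocator:
    """Hands out non-overlapping genome slots in seeded shuffled order.

    Two slot classes are carved out of the contigs up front: long slots for
    30-500 bp deletions and small slots for everything else. Requesting
    more slots than fit raises a capacity error naming the shortfall.
    """

    def __init__(self, genome: GenomeSequence, rng: np.random.Generator,
                 n_small: int, n_long: int):
        small: List[Tuple[str, int]] = []
        long_: List[Tuple[str, int]] = []
        for name, seq in genome.items():
            cursor = EDGE_MARGIN
            end = len(seq) - EDGE_MARGIN
            while len(long_) < n_long and cursor + LONG_SLOT <= end:
                long_.append((name, cursor))
                cursor += LONG_SLOT
            while cursor + SMALL_SLOT <= end:
                small.append((name, cursor))
                cursor += SMALL_SLOT
        if len(long_) < n_long or len(small) < n_small:
            raise RuntimeError(
                "genome too small for requested events: need "
                f"{n_long} long + {n_small} small slots, found "
                f"{len(long_)} long + {len(small)} small")
        self._queues = {
            "small": [small[i] for i in rng.permutation(len(small))],
            "long": [long_[i] for i in rng.permutation(len(long_))],
        }

    def take(self, kind: str = "small") -> Tuple[str, int]:
        queue = self._queues[kind]
        if not queue:
            raise RuntimeError(
                f"genome too small for requested events: {kind} slot supply "
                "exhausted")
        return queue.pop()


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


class _Planter:
    """Plants events into mutable contig arrays for one subject."""

    def __init__(self, genome: GenomeSequence, config: SimulationConfig,
                 rng: np.random.Generator, allocator: _SlotAllocator):
        self.genome = genome
        self.config = config
        self.rng = rng
        self.alloc = allocator
        self.arrays: Dict[str, bytearray] = {
            name: bytearray(seq, "ascii") for name, seq in genome.items()}

    def flush(self) -> None:
        """Write mutated arrays back into the GenomeSequence."""
        for name, arr in self.arrays.items():
            self.genome.contigs[name] = arr.decode("ascii")

    def _set(self, contig: str, idx0: int, base: str) -> None:
        self.arrays[contig][idx0] = ord(base)

    def _get(self, contig: str, idx0: int) -> str:
        return chr(self.arrays[contig][idx0])

    def _slot_anchor(self, kind: str = "small") -> Tuple[str, int]:
        contig, start = self.alloc.take(kind)
        # leave room inside the slot for context on both sides
        jitter = int(self.rng.integers(0, 8))
        return contig, start + 20 + jitter  # 0-based anchor index

    # --- deletions -------------------------------------------------------

    def plant_deletion(self, dlen: int, mh: int) -> IndelRecord:
        """Plant a deletion of ``dlen`` bp with junction microhomology
        exactly ``mh`` (0 for plain events under the "zero" policy)."""
        contig, a0 = self._slot_anchor("long" if dlen >= 30 else "small")
        d0 = a0 + 1                       # deleted interval starts here
        del_seq = self._rand_seq_checked(dlen)
        for j, b in enumerate(del_seq):
            self._set(contig, d0 + j, b)
        # anchor base must mismatch the last deleted base (left-aligned form)
        self._set(contig, a0, _other_base(self.rng, del_seq[-1]))
        cap = min(dlen, 20)
        for j in range(mh):
            self._set(contig, d0 + dlen + j, del_seq[j])
        if mh < cap:
            self._set(contig, d0 + dlen + mh, _other_base(self.rng, del_seq[mh]))
        anchor = self._get(contig, a0)
        return IndelRecord(contig, a0 + 1, anchor + del_seq, anchor)

    def plant_plain_deletion_random_flank(self, dlen: int) -> IndelRecord:
        """Plain deletion over untouched random flank (no mh forcing); used
        to measure incidental microhomology rates."""
        contig, a0 = self._slot_anchor("long" if dlen >= 30 else "small")
        d0 = a0 + 1
        del_seq = self._rand_seq_checked(dlen)
        for j, b in enumerate(del_seq):
            self._set(contig, d0 + j, b)
        self._set(contig, a0, _other_base(self.rng, del_seq[-1]))
        anchor = self._get(contig, a0)
        return IndelRecord(contig, a0 + 1, anchor + del_seq, anchor)

    def _rand_seq_checked(self, n: int) -> str:
        return _rand_seq(self.rng, n)

    # --- insertions ------------------------------------------------------

    def plant_small_insertion(self, templated: bool) -> Tuple[IndelRecord, Dict]:
        """Plant a 1-3 bp insertion; if templated, write a template copy of
        flank+insert+flank into the upstream context. Plain events are
        rejection-resampled until classifier-negative."""
        for _ in range(200):
            contig, a0 = self._slot_anchor()
            ilen = int(self.rng.integers(1, SMALL_INS_MAX + 1))
            ins = _rand_seq(self.rng, ilen)
            # anchor base must mismatch last inserted base (left-aligned form)
            self._set(contig, a0, _other_base(self.rng, ins[-1]))
            params: Dict = {"ins_len": ilen}
            if templated:
                # keep the whole template copy inside the 15 nt upstream
                # window: (k-1) + gap + (k + ins + m) <= 14
                k = int(self.rng.integers(2, 4))
                m = int(self.rng.integers(2, 4))
                gap = int(self.rng.integers(1, 3))
                word = (self.arrays[contig][a0 - k + 1:a0 + 1].decode("ascii")
                        + ins
                        + self.arrays[contig][a0 + 1:a0 + 1 + m].decode("ascii"))
                # template ends `gap` nt before the junction flank start
                t_end = (a0 - k + 1) - gap          # exclusive, 0-based
                t_start = t_end - len(word)
                for j, b in enumerate(word):
                    self._set(contig, t_start + j, b)
                params.update(p2_len=k, mh2_len=m, template_offset=gap)
            rec = IndelRecord(contig, a0 + 1, self._get(contig, a0),
                              self._get(contig, a0) + ins)
            self.flush()
            result = classify_small_insertion(rec, self.genome)
            if templated and result is not None:
                return rec, params
            if not templated and result is None:
                return rec, params
            # accidental signature (or clobbered template): redraw in a new slot
        raise RuntimeError("could not plant small insertion after 200 attempts")

    def plant_large_insertion(self, snapback: bool) -> Tuple[IndelRecord, Dict]:
        for _ in range(200):
            contig, a0 = self._slot_anchor()
            if snapback:
                rep = int(self.rng.integers(7, 13))
                sep = int(self.rng.integers(4, 9))
                tail = int(self.rng.integers(0, 16))
                block = _rand_seq(self.rng, rep)
                ins = (block + _rand_seq(self.rng, sep)
                       + reverse_complement(block) + _rand_seq(self.rng, tail))
                params = {"repeat_len": rep, "separation": sep,
                          "ins_len": len(ins)}
            else:
                ilen = int(self.rng.integers(18, 61))
                ins = _rand_seq(self.rng, ilen)
                params = {"ins_len": ilen}
            self._set(contig, a0, _other_base(self.rng, ins[-1]))
            rec = IndelRecord(contig, a0 + 1, self._get(contig, a0),
                              self._get(contig, a0) + ins)
            result = classify_snapback_insertion(rec)
            if snapback and result is not None:
                return rec, params
            if not snapback and result is None:
                return rec, params
        raise RuntimeError("could not plant large insertion after 200 attempts")


def _slot_demand(config: SimulationConfig) -> Tuple[int, int]:
    """(n_small, n_long) slots one subject needs, with retry slack for the
    rejection-resampled insertion classes."""
    n_long = config.n_pre_long_del + config.n_new_long_del
    n_ins = (config.n_small_ins_pre + config.n_small_ins_new
             + config.n_large_ins_pre + config.n_large_ins_new)
    n_small = (config.n_pre_small_del + config.n_new_small_del
               + config.n_bcell_unique + 2 * n_ins + 50)
    return n_small, n_long


def _make_allocator(genome: GenomeSequence, config: SimulationConfig,
                    rng: np.random.Generator,
                    n_subjects: int = 1, extra_small: int = 0) -> _SlotAllocator:
    n_small, n_long = _slot_demand(config)
    return _SlotAllocator(genome, rng, n_small * n_subjects + extra_small,
                          n_long * n_subjects)


def plant_events(genome: GenomeSequence, config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None,
                 allocator: Optional[_SlotAllocator] = None,
                 subject_label: str = "subject1"
                 ) -> Tuple[IndelSet, IndelSet, SyntheticTruth]:
    """Plant one subject's events into ``genome`` (mutated in place).

    Returns the B-cell set, the LCL set and the ground-truth manifest.
    Pre-existing events appear in both sets; new events only in the LCL set;
    B-cell-unique noise events only in the B-cell set.
    """
    rng = rng or np.random.default_rng(config.seed)
    allocator = allocator or _make_allocator(genome, config, rng)
    planter = _Planter(genome, config, rng, allocator)
    weights = config.mh_weights()
    truth = SyntheticTruth()
    bcell = IndelSet(sample_label=f"{subject_label}_bcell")
    lcl = IndelSet(sample_label=f"{subject_label}_lcl")

    def assign(rec: IndelRecord, cls: str, where: str, params: Dict) -> None:
        if where in ("preexisting", "bcell_only"):
            bcell.add(rec)
        if where in ("preexisting", "new"):
            lcl.add(rec)
        truth.entries.append(TruthEntry(rec.key, cls, where, params))

    def plant_del_batch(n: int, frac: float, bounds: Tuple[int, int],
                        where: str) -> None:
        lo, hi = bounds
        for _ in range(n):
            signature = bool(rng.random() < frac)
            dlen = int(rng.integers(lo, hi + 1))
            if signature:
                mh = int(rng.choice(np.arange(2, 21), p=weights))
                mh = min(mh, dlen, 20)
                rec = planter.plant_deletion(dlen, mh)
                assign(rec, "mh_deletion", where, {"mh": mh, "dlen": dlen})
            elif config.plain_mh_policy == "zero":
                rec = planter.plant_deletion(dlen, 0)
                assign(rec, "plain_deletion", where, {"mh": 0, "dlen": dlen})
            else:
                rec = planter.plant_plain_deletion_random_flank(dlen)
                assign(rec, "plain_deletion", where, {"dlen": dlen})

    plant_del_batch(config.n_pre_small_del, config.mh_fraction_pre, (2, 29),
                    "preexisting")
    plant_del_batch(config.n_new_small_del, config.mh_fraction_new, (2, 29),
                    "new")
    plant_del_batch(config.n_pre_long_del, config.mh_fraction_pre, (30, 500),
                    "preexisting")
    plant_del_batch(config.n_new_long_del, config.mh_fraction_new, (30, 500),
                    "new")

    for n, frac, where in ((config.n_small_ins_pre, config.templated_fraction_pre,
                            "preexisting"),
                           (config.n_small_ins_new, config.templated_fraction_new,
                            "new")):
        for _ in range(n):
            templated = bool(rng.random() < frac)
            rec, params = planter.plant_small_insertion(templated)
            assign(rec, "templated_small_ins" if templated else "plain_small_ins",
                   where, params)

    for n, frac, where in ((config.n_large_ins_pre, config.snapback_fraction_pre,
                            "preexisting"),
                           (config.n_large_ins_new, config.snapback_fraction_new,
                            "new")):
        for _ in range(n):
            snap = bool(rng.random() < frac)
            rec, params = planter.plant_large_insertion(snap)
            assign(rec, "snapback_ins" if snap else "plain_large_ins",
                   where, params)

    for _ in range(config.n_bcell_unique):
        dlen = int(rng.integers(2, 30))
        rec = planter.plant_deletion(dlen, 0)
        assign(rec, "plain_deletion", "bcell_only", {"mh": 0, "dlen": dlen})

    planter.flush()
    log.info("plant_events(%s): bcell=%d lcl=%d truth=%d", subject_label,
             len(bcell), len(lcl), len(truth.entries))
    return bcell, lcl, truth


@dataclass
class SimulatedCohort:
    genome: GenomeSequence
    subjects: List[SubjectCalls]
    truths: List[SyntheticTruth]
    shared_spurious_keys: List[Tuple[str, int, str, str]]


def simulate_cohort(config: SimulationConfig, n_subjects: int = 2,
                    n_shared_spurious: int = 10) -> SimulatedCohort:
    """Full study bundle: one reference, ``n_subjects`` paired call sets,
    plus ``n_shared_spurious`` artifact indels planted into every subject's
    samples (these should be removed by the cross-subject filter)."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_reference(config, rng)
    allocator = _make_allocator(genome, config, rng, n_subjects=n_subjects,
                                extra_small=n_shared_spurious + 10)
    subjects, truths = [], []
    for i in range(n_subjects):
        label = f"subject{i + 1}"
        bcell, lcl, truth = plant_events(genome, config, rng, allocator, label)
        subjects.append(SubjectCalls(label, bcell, lcl))
        truths.append(truth)
    planter = _Planter(genome, config, rng, allocator)
    shared_keys = []
    for _ in range(n_shared_spurious):
        rec = planter.plant_deletion(int(rng.integers(2, 30)), 0)
        shared_keys.append(rec.key)
        for subj in subjects:
            subj.bcell.add(rec)
            subj.lcl.add(rec)
    planter.flush()
    return SimulatedCohort(genome, subjects, truths, shared_keys)


def write_vcf(records: IndelSet, genome: GenomeSequence, path,
              default_qual: float = 60.0) -> None:
    """Write a sorted VCF v4.2 with anchor-base alleles.

    Round-trips through :func:`mmejsig.variants.read_indels`; byte-identical
    across runs for identical inputs.
    """
    order = {name: i for i, name in enumerate(genome.contigs)}
    recs = sorted(records, key=lambda r: (order.get(r.contig, 1 << 30), r.pos,
                                          r.ref_allele, r.alt_allele))
    for rec in recs:
        expected = genome.fetch(rec.contig, rec.pos,
                                rec.pos + len(rec.ref_allele) - 1)
        if expected != rec.ref_allele:
            raise ValueError(f"record inconsistent with reference: {rec} "
                             f"(reference has {expected!r})")
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=mmejsig-simulator\n")
        for name, seq in genome.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in recs:
            qual = rec.qual if rec.qual is not None else default_qual
            qual_str = f"{qual:g}"
            out.write(f"{rec.contig}\t{rec.pos}\t.\t{rec.ref_allele}\t"
                      f"{rec.alt_allele}\t{qual_str}\t.\t.\n")


def write_bundle(config: SimulationConfig, outdir, n_subjects: int = 2,
                 n_shared_spurious: int = 10) -> SimulatedCohort:
    """Simulate and write FASTA + per-subject VCFs + truth manifests."""
    from .genome import write_genome
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config, n_subjects=n_subjects,
                             n_shared_spurious=n_shared_spurious)
    write_genome(cohort.genome, outdir / "reference.fa")
    for subj, truth in zip(cohort.subjects, cohort.truths):
        write_vcf(subj.bcell, cohort.genome, outdir / f"{subj.label}_bcell.vcf")
        write_vcf(subj.lcl, cohort.genome, outdir / f"{subj.label}_lcl.vcf")
        truth.to_json(outdir / f"{subj.label}_truth.json")
    return cohort
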