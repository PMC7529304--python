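import numpy as np
import pytest

from mmejsig.cohort import partition_pre_new
from mmejsig.genome import GenomeSequence
from mmejsig.insertions import (IneligibleInsertionError, SNAPBACK_MIN_LEN,
                                build_insertion_tables, classify_insertions,
                                classify_small_insertion,
                                classify_snapback_insertion,
                                reverse_complement)
from mmejsig.simulate import SimulationConfig, plant_events, simulate_reference
from mmejsig.variants import IndelRecord

from conftest import random_genome

# --- independent brute-force oracles ---------------------------------------

_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _chars_match(a, b):
    return a == b and a in "ACGT"


def oracle_small_positive(left, right, ins, min_flank=2, min_gap=1):
    """Exhaustive (k, m, window position) enumeration with explicit
    character comparison; returns True iff any valid template copy exists."""
    ctx = left + right
    nl = len(left)
    for k in range(min_flank, len(left) + 1):
        for m in range(min_flank, len(right) + 1):
            word = left[nl - k:] + ins + right[:m]
            w = len(word)
            for s in range(0, len(ctx) - w + 1):
                if not all(_chars_match(ctx[s + i], word[i]) for i in range(w)):
                    continue
                before_gap = (nl - k) - (s + w)
                after_gap = s - (nl + m)
                if before_gap >= min_gap or after_gap >= min_gap:
                    return True
    return False


def oracle_snapback_positive(seq, min_repeat=7, min_sep=4):
    """All (i, j, L) triples with explicit base-by-base complement check."""
    n = len(seq)
    for L in range(min_repeat, n + 1):
        for i in range(0, n - L + 1):
            for j in range(i + L + min_sep, n - L + 1):
                ok = True
                for t in range(L):
                    a, b = seq[i + t], seq[j + L - 1 - t]
                    if a not in _RC or _RC[a] != b:
                        ok = False
                        break
                if ok:
                    return True
    return False


def _ins_record(genome, contig, pos, ins):
    anchor = genome.base(contig, pos)
    return IndelRecord(contig, pos, anchor, anchor + ins)


# --- small insertions -------------------------------------------------------

class TestClassifySmallInsertion:
    def test_worked_example_upstream_template(self):
        """A single-G insertion whose junction word AGA+g+AAA recurs
        upstream: positive with P2 = AGA and mh2 = AAA."""
        left = "GCTTAGAGAAATAGA"   # template AGAGAAA at offset 4, gap 1
        right = "AAACGTCGTCGTCGT"
        pad = "CCGG" * 5
        g = GenomeSequence({"c1": pad + left + right + pad})
        rec = _ins_record(g, "c1", len(pad) + 15, "G")
        m = classify_small_insertion(rec, g)
        assert m is not None
        assert m.side == "upstream"
        assert m.p2_len == 3 and m.mh2_len == 3
        assert m.template_offset >= 1

    def test_homopolymer_context_negative(self):
        g = GenomeSequence({"c1": "T" * 15 + "C" * 15})
        rec = _ins_record(g, "c1", 15, "G")
        assert classify_small_insertion(rec, g) is None

    def test_too_long_rejected(self, toy_genome):
        rec = _ins_record(toy_genome, "c1", 4, "ACGT")
        with pytest.raises(IneligibleInsertionError):
            classify_small_insertion(rec, toy_genome)

    def test_contig_edge_negative(self):
        g = GenomeSequence({"c1": "A" * 30})
        rec = _ins_record(g, "c1", 1, "G")  # only 1 nt of upstream flank
        assert classify_small_insertion(rec, g) is None

    def test_matches_bruteforce_enumeration(self, rng):
        """500 random insertions in random context agree with the exhaustive
        (k, m, position) oracle."""
        n_pos = n_checked = 0
        for _ in range(500):
            g = random_genome(rng, length=40)
            pos = int(rng.integers(16, 25))
            ins = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(1, 4))))
            rec = _ins_record(g, "chr1", pos, ins)
            left = g.contigs["chr1"][pos - 15:pos]
            right = g.contigs["chr1"][pos:pos + 15]
            got = classify_small_insertion(rec, g)
            assert (got is not None) == oracle_small_positive(left, right, ins)
            n_checked += 1
            n_pos += got is not None
        assert n_checked == 500 and 0 < n_pos < 500

    def test_match_fields_consistent(self, rng):
        for _ in range(100):
            g = random_genome(rng, length=40)
            pos = int(rng.integers(16, 25))
            rec = _ins_record(g, "chr1", pos, "AT")
            m = classify_small_insertion(rec, g)
            if m is not None:
                assert m.p2_len >= 2 and m.mh2_len >= 2
                assert m.template_offset >= 1
                assert m.side in ("upstream", "downstream")


# --- snapback insertions ----------------------------------------------------

class TestClassifySnapback:
    def test_constructed_inverted_repeat(self, toy_genome):
        ins = "ATCGATC" + "TTTT" + "GATCGAT"  # rc("ATCGATC") == "GATCGAT"
        rec = _ins_record(toy_genome, "c1", 2, ins)
        m = classify_snapback_insertion(rec)
        assert m is not None
        assert m.repeat_len == 7 and m.separation == 4
        assert rec.event_seq[m.first_start:m.first_start + 7] == \
            reverse_complement(
                rec.event_seq[m.second_start:m.second_start + 7])

    def test_poly_a_negative(self, toy_genome):
        rec = _ins_record(toy_genome, "c1", 2, "A" * 20)
        assert classify_snapback_insertion(rec) is None

    def test_length_17_rejected_not_evaluated(self, toy_genome):
        rec = _ins_record(toy_genome, "c1", 2, "ATCGATCTTTTGATCGA")
        assert len(rec.event_seq) == 17
        with pytest.raises(IneligibleInsertionError):
            classify_snapback_insertion(rec)

    def test_minimum_length_constant(self):
        assert SNAPBACK_MIN_LEN == 2 * 7 + 4 == 18

    def test_matches_bruteforce_enumeration(self, rng, toy_genome):
        """500 random insertions of length 18-40 agree with the all-substring
        oracle."""
        n_pos = 0
        for _ in range(500):
            n = int(rng.integers(18, 41))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            rec = _ins_record(toy_genome, "c1", 2, seq)
            got = classify_snapback_insertion(rec)
            assert (got is not None) == oracle_snapback_positive(seq)
            n_pos += got is not None
        assert 0 < n_pos < 500

    def test_strand_symmetry(self, rng, toy_genome):
        """Reverse-complementing the insertion preserves the call."""
        for _ in range(100):
            n = int(rng.integers(18, 40))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            fwd = classify_snapback_insertion(_ins_record(toy_genome, "c1", 2, seq))
            rev = classify_snapback_insertion(
                _ins_record(toy_genome, "c1", 2, reverse_complement(seq)))
            assert (fwd is None) == (rev is None)

    def test_monotone_under_extension(self, rng, toy_genome):
        """Appending nucleotides never turns a positive call negative."""
        base = "ATCGATC" + "TTTT" + "GATCGAT"
        for _ in range(50):
            tail = "".join(rng.choice(list("ACGT"),
                                      size=int(rng.integers(0, 20))))
            rec = _ins_record(toy_genome, "c1", 2, base + tail)
            assert classify_snapback_insertion(rec) is not None

    def test_n_disqualifies_repeat(self, toy_genome):
        ins = "ATCNATC" + "TTTT" + "GATNGAT" + "ACGT"
        rec = _ins_record(toy_genome, "c1", 2, ins)
        assert classify_snapback_insertion(rec) is None


# --- bucket routing and summaries -------------------------------------------

class TestInsertionTables:
    def test_every_insertion_in_exactly_one_bucket(self, rng):
        g = random_genome(rng, length=3000)
        recs = []
        for i, n in enumerate([1, 2, 3, 4, 10, 17, 18, 25]):
            pos = 100 + 100 * i
            ins = "".join(rng.choice(list("ACGT"), size=n))
            recs.append(_ins_record(g, "chr1", pos, ins))
        calls = classify_insertions(recs, g)
        buckets = [c.bucket for c in calls]
        assert buckets == ["small"] * 3 + ["unclassified"] * 3 + ["snapback"] * 2
        assert len(calls) == len(recs)

    def test_summaries_match_truth_manifest(self):
        """Planted snapback rates are recovered exactly and the pre-vs-new
        difference is significant."""
        cfg = SimulationConfig(seed=31, genome_length=150_000, n_contigs=1,
                               n_pre_small_del=0, n_new_small_del=0,
                               n_pre_long_del=0, n_new_long_del=0,
                               n_small_ins_pre=50, n_small_ins_new=50,
                               n_large_ins_pre=100, n_large_ins_new=100,
                               snapback_fraction_pre=0.1,
                               snapback_fraction_new=0.4,
                               n_bcell_unique=0)
        genome = simulate_reference(cfg)
        bcell, lcl, truth = plant_events(genome, cfg)
        part = partition_pre_new(bcell, lcl)
        small, snap, _, _ = build_insertion_tables(part, genome)
        want = {("snapback_ins", "preexisting"): 0, ("snapback_ins", "new"): 0,
                ("templated_small_ins", "preexisting"): 0,
                ("templated_small_ins", "new"): 0}
        for e in truth.entries:
            k = (e.event_class, e.set_assignment)
            if k in want:
                want[k] += 1
        assert snap.pos_pre == want[("snapback_ins", "preexisting")]
        assert snap.pos_new == want[("snapback_ins", "new")]
        assert small.pos_pre == want[("templated_small_ins", "preexisting")]
        assert small.pos_new == want[("templated_small_ins", "new")]
        assert snap.p_value < 1e-4
        assert snap.mean_len_pre > 0 and snap.mean_len_new > 0

    def test_empty_sets_give_na(self, toy_genome):
        from mmejsig.variants import IndelSet
        from mmejsig.cohort import PartitionResult
        part = PartitionResult(IndelSet([]), IndelSet([]))
        small, snap, pre_c, new_c = build_insertion_tables(part, toy_genome)
        assert small.p_label == "NA" and snap.p_label == "NA"
        assert small.n_pre == 0 and snap.n_new == 0

    def test_identical_sets_give_p_one(self, rng):
        g = random_genome(rng, length=2000)
        recs = [_ins_record(g, "chr1", 100 + 50 * i,
                            "".join(rng.choice(list("ACGT"), size=2)))
                for i in range(10)]
        from mmejsig.variants import IndelSet
        from mmejsig.cohort import PartitionResult
        part = PartitionResult(IndelSet(recs), IndelSet(recs))
        small, snap, _, _ = build_insertion_tables(part, g)
        if small.n_pre and not np.isnan(small.p_value):
            assert small.p_value == pytest.approx(1.0)
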