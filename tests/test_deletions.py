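import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmejsig.cohort import PartitionResult, partition_pre_new
from mmejsig.deletions import (build_deletion_table, microhomology_length,
                               score_deletion, score_deletions,
                               table_to_dataframe)
from mmejsig.genome import GenomeSequence
from mmejsig.simulate import SimulationConfig, plant_events, simulate_reference
from mmejsig.variants import IndelRecord, IndelSet


def oracle_prefix_match(a, b, cap=20):
    """Independent position-by-position scan; N matches nothing."""
    k = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N" or k >= cap:
            break
        k += 1
    return min(k, cap)


class TestMicrohomologyLength:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGA", 3),
        ("TTTT", "GAAA", 0),
        ("ACG", "ACG", 3),
        ("ACG", "AC", 2),          # shorter flank caps the score
        ("ANGT", "ANGT", 1),       # N never matches, even N vs N
        ("A" * 30, "A" * 30, 20),  # capped at 20
    ])
    def test_examples(self, a, b, expected):
        assert microhomology_length(a, b) == expected

    def test_empty_deletion_rejected(self):
        with pytest.raises(ValueError):
            microhomology_length("", "ACGT")

    @settings(derandomize=True, max_examples=300)
    @given(a=st.text(alphabet="ACGTN", min_size=1, max_size=40),
           b=st.text(alphabet="ACGTN", min_size=0, max_size=40))
    def test_matches_bruteforce_scan(self, a, b):
        assert microhomology_length(a, b) == oracle_prefix_match(a, b)


class TestScoreDeletion:
    def test_full_homology_junction(self):
        # ...G|ACG|ACGTT...: deleting ACG leaves flank starting ACG
        g = GenomeSequence({"c1": "TTGACGACGTTAA"})
        rec = IndelRecord("c1", 3, "GACG", "G")
        scored = score_deletion(rec, g)
        assert scored.mh_len == 3 and scored.size_class == "small"

    def test_no_homology(self):
        g = GenomeSequence({"c1": "TTGATGGCCA"})
        rec = IndelRecord("c1", 3, "GAT", "G")  # deletes AT, flank GG
        assert score_deletion(rec, g).mh_len == 0

    def test_contig_edge_caps_by_flank(self):
        g = GenomeSequence({"c1": "TGACGAC"})  # deletes ACG, flank "AC" only
        rec = IndelRecord("c1", 2, "GACG", "G")
        assert score_deletion(rec, g).mh_len == 2

    def test_out_of_range_lengths_not_scored(self):
        g = GenomeSequence({"c1": "A" * 1200})
        too_short = IndelRecord("c1", 2, "AA", "A")      # 1 bp
        too_long = IndelRecord("c1", 2, "A" * 502, "A")  # 501 bp
        assert score_deletions([too_short, too_long], g) == []

    def test_planted_homology_recovered(self, rng):
        """Deletions planted with designed junction homology k are recovered
        with exactly that score."""
        cfg = SimulationConfig(seed=5, genome_length=150_000, n_contigs=1,
                               n_pre_small_del=60, n_new_small_del=60,
                               n_pre_long_del=10, n_new_long_del=10,
                               n_small_ins_pre=0, n_small_ins_new=0,
                               n_large_ins_pre=0, n_large_ins_new=0,
                               n_bcell_unique=0)
        genome = simulate_reference(cfg)
        bcell, lcl, truth = plant_events(genome, cfg)
        by_key = truth.by_key()
        scored = score_deletions(lcl.records(), genome)
        assert len(scored) == len(lcl)
        for d in scored:
            assert d.mh_len == by_key[d.record.key].params["mh"]


def _partition_from_simulation(seed=11, **overrides):
    cfg = SimulationConfig(seed=seed, genome_length=250_000, n_contigs=1,
                           n_small_ins_pre=0, n_small_ins_new=0,
                           n_large_ins_pre=0, n_large_ins_new=0,
                           n_bcell_unique=0, **overrides)
    genome = simulate_reference(cfg)
    bcell, lcl, _ = plant_events(genome, cfg)
    return genome, partition_pre_new(bcell, lcl)


class TestBuildDeletionTable:
    def test_short_deletions_excluded_below_threshold(self):
        """A 3 bp deletion cannot carry a 4 bp match and is excluded from the
        T=4 row's considered counts."""
        g = GenomeSequence({"c1": "TTGACTGGCCAGGCCATTGGCCAATT"})
        rec = IndelRecord("c1", 3, "GACT", "G")  # 3 bp deletion
        part = PartitionResult(IndelSet([rec]), IndelSet([rec]))
        rows = build_deletion_table(part, g, "small")
        by_T = {r.T: r for r in rows}
        assert by_T[2].n_pre == 1 and by_T[3].n_pre == 1
        assert by_T[4].n_pre == 0 and by_T[4].label == "NA"

    def test_empty_partition_gives_na_rows(self, toy_genome):
        part = PartitionResult(IndelSet([]), IndelSet([]))
        rows = build_deletion_table(part, toy_genome, "small")
        assert len(rows) == 19
        assert all(r.label == "NA" and r.n_pre == 0 and r.n_new == 0
                   for r in rows)

    def test_counts_match_bruteforce_and_are_monotone(self):
        genome, part = _partition_from_simulation(
            n_pre_small_del=150, n_new_small_del=150,
            n_pre_long_del=0, n_new_long_del=0)
        from mmejsig.deletions import score_deletions
        pre = score_deletions(part.preexisting.records(), genome)
        new = score_deletions(part.new.records(), genome)
        rows = build_deletion_table(part, genome, "small")
        prev = None
        for row in rows:
            T = row.T
            assert row.n_pre == sum(1 for d in pre if d.record.event_len >= T)
            assert row.mh_pre == sum(1 for d in pre
                                     if d.record.event_len >= T and d.mh_len >= T)
            assert row.n_new == sum(1 for d in new if d.record.event_len >= T)
            assert row.mh_new == sum(1 for d in new
                                     if d.record.event_len >= T and d.mh_len >= T)
            if prev is not None:
                assert row.n_pre <= prev.n_pre and row.n_new <= prev.n_new
                assert row.mh_pre <= prev.mh_pre and row.mh_new <= prev.mh_new
            prev = row

    def test_long_class_totals_constant_across_thresholds(self):
        genome, part = _partition_from_simulation(
            n_pre_small_del=0, n_new_small_del=0,
            n_pre_long_del=40, n_new_long_del=40)
        rows = build_deletion_table(part, genome, "long")
        assert len({r.n_pre for r in rows}) == 1
        assert len({r.n_new for r in rows}) == 1
        assert rows[0].n_pre == 40 and rows[0].n_new == 40

    def test_planted_fraction_difference_detected(self):
        """200 pre at 30% mh>=2 vs 200 new at 60%: recovered fractions equal
        the truth-manifest rates and the enrichment is highly significant."""
        cfg = SimulationConfig(seed=23, genome_length=250_000, n_contigs=1,
                               n_pre_small_del=200, n_new_small_del=200,
                               n_pre_long_del=0, n_new_long_del=0,
                               mh_fraction_pre=0.3, mh_fraction_new=0.6,
                               n_small_ins_pre=0, n_small_ins_new=0,
                               n_large_ins_pre=0, n_large_ins_new=0,
                               n_bcell_unique=0)
        genome = simulate_reference(cfg)
        bcell, lcl, truth = plant_events(genome, cfg)
        part = partition_pre_new(bcell, lcl)
        row = build_deletion_table(part, genome, "small")[0]
        n_sig = {"preexisting": 0, "new": 0}
        n_tot = {"preexisting": 0, "new": 0}
        for e in truth.entries:
            n_tot[e.set_assignment] += 1
            if e.event_class == "mh_deletion":
                n_sig[e.set_assignment] += 1
        assert row.mh_pre == n_sig["preexisting"]
        assert row.mh_new == n_sig["new"]
        assert abs(row.frac_pre - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 200)
        assert abs(row.frac_new - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 200)
        assert row.p_value < 1e-6

    def test_report_columns_and_determinism(self):
        genome, part = _partition_from_simulation(
            n_pre_small_del=50, n_new_small_del=50,
            n_pre_long_del=0, n_new_long_del=0)
        rows1 = build_deletion_table(part, genome, "small")
        rows2 = build_deletion_table(part, genome, "small")
        df = table_to_dataframe(rows1)
        assert list(df.columns) == ["minimum_mh", "pre_existing_deletions",
                                    "pre_with_mh", "pre_fraction",
                                    "new_deletions", "new_with_mh",
                                    "new_fraction", "p", "p_raw"]
        assert df.to_csv() == table_to_dataframe(rows2).to_csv()
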