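"""The three filter families plus the flag-only tests."""

import math

import pytest

from fuseqlite.feq import FragmentRecord, FusionGeneCandidate
from fuseqlite.filters import (FilterConfig, annotate_special_genes,
                               build_similarity_reference, general_filter,
                               inverted_fusion_filter, load_gene_pairs,
                               mr_sr_consistency, positional_distribution,
                               positional_filter, robust_z,
                               shared_support_screen, similarity_filter)
from fuseqlite.quasimap import MappingParams, build_index
from fuseqlite.simdata import simulate_transcriptome
from fuseqlite.splitread import JunctionBreak

from conftest import make_transcriptome, random_seq


def _cand(g5="gA", g3="gB", support=5, corrected=4.0, sr=0, frags=None, score=0.0):
    c = FusionGeneCandidate(g5, g3, support_count=support, corrected_count=corrected,
                            sr_count=sr, score=score)
    c.fragments = frags or [FragmentRecord(f"r{i}", i * 10, i * 7, "t5", "t3")
                            for i in range(support)]
    return c


@pytest.fixture(scope="module")
def anno_t():
    return make_transcriptome([
        ("t1", "gA", "1", "+", [(100_000, 101_000)], random_seq(100, 1)),
        ("t2", "gB", "2", "+", [(500_000, 501_000)], random_seq(100, 2)),
        ("t3", "gM", "MT", "+", [(1_000, 2_000)], random_seq(100, 3)),
        ("t4", "gNC", "3", "+", [(9_000, 10_000)], random_seq(100, 4)),
        ("t5", "gNear", "1", "+", [(106_000, 107_000)], random_seq(100, 5)),
    ])


class TestGeneralFilter:
    def setup_method(self):
        self.cfg = FilterConfig()

    def test_passing_candidate(self, anno_t):
        ok, reasons = general_filter(_cand(), anno_t, self.cfg)
        assert ok and not reasons

    def test_mitochondrial_chromosome_dropped(self, anno_t):
        ok, reasons = general_filter(_cand(g3="gM"), anno_t, self.cfg)
        assert not ok and any(r.startswith("chromosome") for r in reasons)

    def test_non_coding_partner_dropped(self, anno_t):
        anno_t.genes["gNC"].biotype = "lincRNA"
        ok, reasons = general_filter(_cand(g3="gNC"), anno_t, self.cfg)
        assert not ok and any(r.startswith("biotype") for r in reasons)
        ok, _ = general_filter(
            _cand(g3="gNC"), anno_t,
            FilterConfig(require_protein_coding=False),
        )
        assert ok

    def test_close_same_chromosome_genes_dropped(self, anno_t):
        # gA ends at 101_000, gNear starts at 106_000: ~5 kb < 100 kb
        ok, reasons = general_filter(_cand(g3="gNear"), anno_t, self.cfg)
        assert not ok and any(r.startswith("distance") for r in reasons)

    def test_different_chromosomes_always_pass_distance(self, anno_t):
        ok, _ = general_filter(_cand(), anno_t, FilterConfig(min_gene_distance=10**9))
        assert ok

    def test_low_mapped_read_support_dropped(self, anno_t):
        ok, reasons = general_filter(_cand(support=1), anno_t, self.cfg)
        assert not ok and any(r.startswith("mr_support") for r in reasons)


class TestInvertedFusionFilter:
    def test_higher_scoring_direction_kept(self):
        a = _cand("gA", "gB", score=10.0)
        b = _cand("gB", "gA", score=2.0)
        out = inverted_fusion_filter([a, b])
        assert out == [a]

    def test_single_direction_unchanged(self):
        a = _cand("gA", "gB", score=5.0)
        assert inverted_fusion_filter([a]) == [a]

    def test_score_tie_drops_both_as_circular(self):
        a = _cand("gA", "gB", score=4.0)
        b = _cand("gB", "gA", score=4.0)
        out = inverted_fusion_filter([a, b])
        assert out == []
        assert "circular" in a.flags and "circular" in b.flags


class TestSimilarityReference:
    def test_planted_shared_exon_pair_detected(self):
        t = simulate_transcriptome(n_genes=4, tx_per_gene=1, seed=9,
                                   shared_exon_len=600)
        cfg = FilterConfig(sim_read_count=40, sim_seed=5)
        idx = build_index(t, MappingParams(k=31, r=100))
        ref = build_similarity_reference(t, cfg, idx=idx)
        assert frozenset({"GENE0001", "GENE0002"}) in ref

    def test_unique_sequences_give_empty_reference(self):
        t = simulate_transcriptome(n_genes=4, tx_per_gene=1, seed=10)
        cfg = FilterConfig(sim_read_count=40, sim_seed=5)
        idx = build_index(t, MappingParams(k=31, r=100))
        assert build_similarity_reference(t, cfg, idx=idx) == set()

    def test_same_seed_reproduces_reference(self):
        t = simulate_transcriptome(n_genes=4, tx_per_gene=1, seed=9,
                                   shared_exon_len=600)
        cfg = FilterConfig(sim_read_count=40, sim_seed=5)
        idx = build_index(t, MappingParams(k=31, r=100))
        assert build_similarity_reference(t, cfg, idx=idx) == \
            build_similarity_reference(t, cfg, idx=idx)


class TestSimilarityFilter:
    def test_paralog_pair_dropped(self, tmp_path):
        db_path = tmp_path / "paralogs.tsv"
        db_path.write_text("gA\tgB\ngX\tgY\n")
        db = load_gene_pairs(db_path)
        ok, reasons = similarity_filter(_cand(), set(), paralog_db=db)
        assert not ok and "similarity:paralog" in reasons

    def test_simulated_reference_pair_dropped(self):
        ok, reasons = similarity_filter(_cand(), {frozenset({"gA", "gB"})})
        assert not ok and "similarity:simulated" in reasons

    def test_empty_references_keep(self):
        ok, reasons = similarity_filter(_cand(), set())
        assert ok and not reasons

    def test_shared_support_drops_lower_scoring(self):
        frags = [FragmentRecord(f"r{i}", i, i, "t", "t") for i in range(10)]
        hi = _cand("gA", "gB", frags=list(frags), score=9.0)
        lo = _cand("gA", "gC", frags=list(frags[:9]) + [FragmentRecord("x", 0, 0, "t", "t")],
                   score=4.0)
        out = shared_support_screen([hi, lo], frac=0.5)
        assert out == [hi]

    def test_disjoint_support_keeps_both(self):
        a = _cand("gA", "gB", frags=[FragmentRecord(f"a{i}", i, i, "t", "t") for i in range(5)],
                  score=5.0)
        b = _cand("gA", "gC", frags=[FragmentRecord(f"b{i}", i, i, "t", "t") for i in range(5)],
                  score=4.0)
        assert shared_support_screen([a, b]) == [a, b]


class TestPositionalFilter:
    def setup_method(self):
        self.cfg = FilterConfig()

    def test_pcr_duplicates_collapse_below_support(self, anno_t):
        frags = [FragmentRecord(f"r{i}", 100, 200, "t1", "t2") for i in range(10)]
        c = _cand(support=10, frags=frags)
        pd = positional_distribution(c, anno_t, read_len=100)
        ok, reasons = positional_filter(c, pd, self.cfg)
        assert not ok
        assert c.support_count == 1
        assert any(r.startswith("dedup") for r in reasons)

    def test_fragment_length_outlier_removed_by_robust_z(self, anno_t):
        # 19 fragments implying ~200 bp, one implying ~2000 bp
        frags = [FragmentRecord(f"r{i}", 400 - i, i, "t1", "t2") for i in range(19)]
        frags.append(FragmentRecord("r19", 400 - 1800, 19, "t1", "t2"))
        c = _cand(support=20, frags=frags)
        c.breakpoint = JunctionBreak("gA", "gB", "t1", "t2", "1", "2",
                                     100_500, 500_000, 500, 1)
        pd = positional_distribution(c, anno_t, read_len=100)
        assert max(robust_z(__import__("numpy").array(pd.implied_fragment_lengths))) > 5
        ok, reasons = positional_filter(c, pd, self.cfg)
        assert ok
        assert c.support_count == 19
        assert any(r.startswith("fraglen") for r in reasons)

    def test_equal_fragment_lengths_all_pass_despite_zero_mad(self, anno_t):
        frags = [FragmentRecord(f"r{i}", 300, 10 + i, "t1", "t2") for i in range(5)]
        c = _cand(support=5, frags=frags)
        c.breakpoint = JunctionBreak("gA", "gB", "t1", "t2", "1", "2",
                                     100_500, 500_000, 500, 1)
        pd = positional_distribution(c, anno_t, read_len=100)
        pd.implied_fragment_lengths = [250.0] * 5
        ok, _ = positional_filter(c, pd, self.cfg)
        assert ok and c.support_count == 5

    def test_close_breakpoints_same_chromosome_dropped(self, anno_t):
        c = _cand()
        c.breakpoint = JunctionBreak("gA", "gNear", "t1", "t5", "1", "1",
                                     100_500, 103_500, 1, 1)
        pd = positional_distribution(c, anno_t, read_len=100)
        ok, reasons = positional_filter(c, pd, self.cfg)
        assert not ok and any(r.startswith("junction_distance") for r in reasons)

    def test_zero_thresholds_and_no_collapse_is_identity(self, anno_t):
        cfg = FilterConfig(min_mr_support=0, min_sr_support=0, min_score=0,
                           dup_collapse=False, min_gene_distance=0,
                           min_junction_distance=0)
        frags = [FragmentRecord(f"r{i}", 100, 200, "t1", "t2") for i in range(3)]
        c = _cand(support=3, corrected=3.0, frags=frags)
        pd = positional_distribution(c, anno_t, read_len=100)
        ok, reasons = positional_filter(c, pd, cfg)
        assert ok and not reasons and c.support_count == 3
        ok, reasons = general_filter(c, anno_t, cfg)
        assert ok
        ok, reasons = similarity_filter(c, set())
        assert ok


class TestConsistencyAndAnnotation:
    def test_single_evidence_type_not_flagged(self):
        c = _cand(support=10, sr=0)
        assert mr_sr_consistency(c, FilterConfig()) is False
        assert not c.flags

    def test_balanced_evidence_consistent(self):
        c = _cand(support=50, sr=48)
        assert mr_sr_consistency(c, FilterConfig()) is False

    def test_extreme_imbalance_flagged_not_dropped(self):
        c = _cand(support=200, sr=1)
        assert mr_sr_consistency(c, FilterConfig()) is True
        assert "mr_sr_inconsistent" in c.flags

    def test_special_gene_flags_added_never_dropping(self):
        c = _cand("gA", "gB")
        added = annotate_special_genes(c, {"ribosomal": {"gA"}, "mito": {"gB"}})
        assert added == {"ribosomal:gA", "mito:gB"}
        assert annotate_special_genes(_cand(), {}) == set()
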