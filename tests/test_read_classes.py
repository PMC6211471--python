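"""Read-pair classification into concordant / mapped read / split read."""

import pytest

from fuseqlite.quasimap import MappingParams, build_index, map_pair
from fuseqlite.read_classes import (CONCORDANT, MAPPED_READ, OTHER, SPLIT_READ,
                                    classify_pair, extract_split_info)
from fuseqlite.reference import revcomp

from conftest import make_transcriptome, random_seq


def pad(n: int, avoid: str) -> str:
    """Unmappable homopolymer filler guaranteed to mismatch its first base."""
    base = "A" if avoid != "A" else "C"
    return base * n


@pytest.fixture(scope="module")
def two_gene_setup():
    t = make_transcriptome([
        ("txA", "gA", "1", "+", None, random_seq(800, 21)),
        ("txB", "gB", "2", "+", None, random_seq(800, 22)),
    ])
    params = MappingParams(k=21, r=50)
    return t, params, build_index(t, params)


class TestClassifyPair:
    def test_concordant_when_mates_share_transcript(self, two_gene_setup):
        t, params, idx = two_gene_setup
        seq = t.transcripts["txA"].sequence
        pm = map_pair(seq[0:50], revcomp(seq[150:200]), idx)
        assert classify_pair(pm, params, t).label == CONCORDANT

    def test_mapped_read_at_near_full_threshold(self, two_gene_setup):
        # r=50, k=21: exactly 28 matched bases per mate qualifies (r - k - 1)
        t, params, idx = two_gene_setup
        a, b = t.transcripts["txA"].sequence, t.transcripts["txB"].sequence
        m1 = a[100:128] + pad(22, a[128])
        m2 = revcomp(b[300:328] + pad(22, b[328]))
        pm = map_pair(m1, m2, idx)
        assert classify_pair(pm, params, t).label == MAPPED_READ

    def test_below_threshold_is_other(self, two_gene_setup):
        t, params, idx = two_gene_setup
        a, b = t.transcripts["txA"].sequence, t.transcripts["txB"].sequence
        m1 = a[100:127] + pad(23, a[127])  # 27 < 28
        m2 = revcomp(b[300:328] + pad(22, b[328]))
        pm = map_pair(m1, m2, idx)
        assert classify_pair(pm, params, t).label == OTHER

    def test_split_read_with_anchored_mate(self, two_gene_setup):
        t, params, idx = two_gene_setup
        a, b = t.transcripts["txA"].sequence, t.transcripts["txB"].sequence
        split = a[200:225] + b[400:425]  # 25|25, both >= k
        anchor = revcomp(a[100:150])  # fully inside gA
        pm = map_pair(split, anchor, idx)
        pc = classify_pair(pm, params, t)
        assert pc.label == SPLIT_READ
        assert pc.split_mate == 1

    def test_split_requires_k_bases_each_side(self, two_gene_setup):
        t, params, idx = two_gene_setup
        a, b = t.transcripts["txA"].sequence, t.transcripts["txB"].sequence
        # 25|20: 3' side < k=21 and neither side reaches r-k-1=28
        split = a[200:225] + b[400:420] + pad(5, b[420])
        pm = map_pair(split, revcomp(a[100:150]), idx)
        assert classify_pair(pm, params, t).label == OTHER

    def test_split_rejected_when_anchor_in_third_gene(self):
        t = make_transcriptome([
            ("txA", "gA", "1", "+", None, random_seq(800, 31)),
            ("txB", "gB", "2", "+", None, random_seq(800, 32)),
            ("txC", "gC", "3", "+", None, random_seq(800, 33)),
        ])
        params = MappingParams(k=21, r=50)
        idx = build_index(t, params)
        split = t.transcripts["txA"].sequence[200:225] + \
            t.transcripts["txB"].sequence[400:425]
        pm = map_pair(split, revcomp(t.transcripts["txC"].sequence[100:150]), idx)
        assert classify_pair(pm, params, t).label == OTHER

    def test_split_detection_needs_small_k(self):
        assert not MappingParams(k=31, r=60).split_capable
        assert MappingParams(k=21, r=50).split_capable


class TestExtractSplitInfo:
    def test_evidence_fields_for_split_fixture(self, two_gene_setup):
        t, params, idx = two_gene_setup
        a, b = t.transcripts["txA"].sequence, t.transcripts["txB"].sequence
        # choose a junction whose flanks mismatch so segments stop exactly there
        assert a[225] != b[400]
        split = a[200:225] + b[400:425]
        pm = map_pair(split, revcomp(a[100:150]), idx, read_id="rd1")
        e = extract_split_info(pm.mapping1, pm.mapping2, pm, params, t)
        assert e.genes5 == {"gA"} and e.genes3 == {"gB"}
        assert ("txA", 200) in e.tx5_hits and ("txB", 400) in e.tx3_hits
        assert (e.qstart5, e.qend5) == (0, 25)
        assert (e.qstart3, e.qend3) == (25, 50)
        assert e.mate_anchor == ("txA", 100)

    def test_multi_isoform_hits_recorded_under_one_gene(self):
        shared = random_seq(400, 41)
        t = make_transcriptome([
            ("txA1", "gA", "1", "+", None, shared + random_seq(200, 42)),
            ("txA2", "gA", "1", "+", None, shared + random_seq(200, 43)),
            ("txB", "gB", "2", "+", None, random_seq(800, 44)),
        ])
        params = MappingParams(k=21, r=50)
        idx = build_index(t, params)
        split = shared[100:125] + t.transcripts["txB"].sequence[300:325]
        pm = map_pair(split, revcomp(shared[200:250]), idx, read_id="rd2")
        e = extract_split_info(pm.mapping1, pm.mapping2, pm, params, t)
        assert e.genes5 == {"gA"}
        assert {tid for tid, _ in e.tx5_hits} == {"txA1", "txA2"}

    def test_non_split_mate_rejected(self, two_gene_setup):
        t, params, idx = two_gene_setup
        seq = t.transcripts["txA"].sequence
        pm = map_pair(seq[0:50], revcomp(seq[150:200]), idx)
        with pytest.raises(ValueError):
            extract_split_info(pm.mapping1, pm.mapping2, pm, params, t)


class TestNoiseFreeSimulationInvariant:
    """Sweep a fragment across an implanted junction and check every
    classification against the threshold geometry computed independently:
    a mate matching >= r-k-1 bases of one transcript enters its hit set,
    shared hits make the pair concordant, disjoint gene hits make it a
    mapped read, and a mate with >= k bases on each side of the junction
    (anchored by its mate) is a split read."""

    def test_sweep_matches_threshold_geometry(self):
        r, k, fl = 50, 21, 160
        thr = r - k - 1
        a, b = random_seq(1000, 51), random_seq(1000, 52)
        b5 = 500
        b3 = next(x for x in range(300, 320) if b[x] != a[b5] and b[x - 1] != a[b5 - 1])
        t = make_transcriptome([
            ("txA", "gA", "1", "+", None, a),
            ("txB", "gB", "2", "+", None, b),
        ])
        params = MappingParams(k=k, r=r)
        idx = build_index(t, params)
        fusion = a[:b5] + b[b3:]

        def side_matches(five_len: int, three_len: int) -> tuple[int, int]:
            m5 = five_len if five_len >= k else 0
            m3 = three_len if three_len >= k else 0
            return m5, m3

        for start in range(b5 - fl + 1, b5):
            j = b5 - start  # 5'-side bases inside the fragment
            frag = fusion[start : start + fl]
            pm = map_pair(frag[:r], revcomp(frag[-r:]), idx)
            label = classify_pair(pm, params, t).label

            f1 = min(j, r)
            m1_5, m1_3 = side_matches(f1, r - f1)
            t3 = min(fl - j, r)
            m2_5, m2_3 = side_matches(r - t3, t3)
            T1 = {g for g, m in (("gA", m1_5), ("gB", m1_3)) if m >= thr}
            T2 = {g for g, m in (("gA", m2_5), ("gB", m2_3)) if m >= thr}
            if T1 & T2:
                expected = CONCORDANT
            elif T1 and T2:
                expected = MAPPED_READ
            elif (min(f1, r - f1) >= k and T2) or (min(t3, r - t3) >= k and T1):
                expected = SPLIT_READ
            else:
                expected = OTHER
            assert label == expected, f"start={start} j={j}: {label} != {expected}"
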