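"""Read mapping: minimizer index, chaining, categories, mapq, filtering
and locus-read extraction (with brute-force oracles)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tylocus import mapping, util
from tylocus.mapping import ChainAlignment


@pytest.fixture(scope="module")
def ref(root_locus=None):
    rng = np.random.default_rng(11)
    return util.random_dna(rng, 12000)


@pytest.fixture(scope="module")
def index(ref):
    return mapping.index_reference(ref)


class TestIndex:
    def test_ref_shorter_than_k_errors(self):
        with pytest.raises(ValueError):
            mapping.index_reference("ACGT", k=15)

    def test_single_kmer_reference(self):
        idx = mapping.index_reference("ACGTACGTACGTACG", k=15, w=1)
        assert sum(len(v) for v in idx.table.values()) == 1
        assert next(iter(idx.table.values()))[0][0] == 0

    def test_polyA_one_distinct_minimizer(self):
        idx = mapping.index_reference("A" * 200, k=15, w=10)
        assert len(idx.table) == 1

    def test_minimizer_density_bounds(self, ref, index):
        npos = sum(len(v) for v in index.table.values())
        density = npos / (len(ref) - index.k + 1)
        # expected 2/(w+1) ~ 0.18 for w=10; assert broad [1/w, 2/w]
        assert 1 / index.w <= density <= 2 / index.w


class TestMapRead:
    def test_exact_substring_primary(self, ref, index):
        read = ref[3000:5000]
        alns = mapping.map_read("r", read, index, ref)
        a = [x for x in alns if x.category == "primary"][0]
        assert a.identity == 1.0 and a.mapq == 60 and a.strand == "+"
        assert a.ref_start == 3000 and a.ref_end == 5000
        # covers >= 99% of the read
        assert (a.read_end - a.read_start) >= 0.99 * len(read)

    def test_reverse_complement(self, ref, index):
        alns = mapping.map_read("r", util.revcomp(ref[3000:5000]), index, ref)
        a = [x for x in alns if x.category == "primary"][0]
        assert a.strand == "-" and a.ref_start == 3000 and a.ref_end == 5000

    def test_split_read_primary_plus_supplementary(self, ref, index):
        rng = np.random.default_rng(1)
        read = ref[2000:4000] + util.random_dna(rng, 6000) + ref[4000:6000]
        alns = mapping.map_read("r", read, index, ref)
        cats = sorted(a.category for a in alns)
        assert cats == ["primary", "supplementary"]
        ivs = sorted((a.ref_start, a.ref_end) for a in alns)
        assert abs(ivs[0][0] - 2000) <= 50 and abs(ivs[0][1] - 4000) <= 50
        assert abs(ivs[1][0] - 4000) <= 50 and abs(ivs[1][1] - 6000) <= 50

    def test_exact_duplication_gives_mapq_zero(self, ref):
        dup = ref[:6000] + ref[2000:4000] + ref[6000:]
        idx = mapping.index_reference(dup)
        alns = mapping.map_read("r", ref[2500:3500], idx, dup)
        prim = [a for a in alns if a.category == "primary"][0]
        assert prim.mapq == 0

    def test_unmapped_read_empty(self, ref, index):
        rng = np.random.default_rng(2)
        assert mapping.map_read("r", util.random_dna(rng, 500), index, ref) == []

    def test_one_primary_and_categories_partition(self, ref, index):
        rng = np.random.default_rng(3)
        read = ref[1000:3000] + util.random_dna(rng, 4000) + ref[7000:9000]
        alns = mapping.map_read("r", read, index, ref)
        assert sum(a.category == "primary" for a in alns) == 1
        assert all(a.category in ("primary", "secondary", "supplementary")
                   for a in alns)


def _random_alignments(rng, n, ref_len=10000):
    cats = ["primary", "secondary", "supplementary"]
    out = []
    for i in range(n):
        s = int(rng.integers(0, ref_len - 10))
        e = int(rng.integers(s + 1, min(ref_len, s + 3000) + 1))
        out.append(ChainAlignment(
            read_id=f"r{rng.integers(0, max(1, n // 2))}", ref_id="ref",
            strand="+",
            read_start=0, read_end=e - s, ref_start=s, ref_end=e,
            ops=f"{e - s}=", score=e - s,
            mapq=int(rng.integers(0, 61)), category=cats[rng.integers(0, 3)]))
    return out


class TestFilterAndExtract:
    def test_supplementary_high_mapq_removed(self):
        a = _random_alignments(np.random.default_rng(0), 1)[0]
        a.category, a.mapq = "supplementary", 60
        assert mapping.filter_alignments([a]) == []

    def test_mapq_boundary(self):
        a = _random_alignments(np.random.default_rng(0), 1)[0]
        a.category = "primary"
        a.mapq = 29
        assert mapping.filter_alignments([a]) == []
        a.mapq = 30
        assert mapping.filter_alignments([a]) == [a]

    def test_empty_input(self):
        assert mapping.filter_alignments([]) == []
        assert mapping.extract_locus_reads([], (10, 20)) == set()

    def test_contained_alignment_excluded(self):
        a = _random_alignments(np.random.default_rng(0), 1)[0]
        a.ref_start, a.ref_end = 120, 180
        assert mapping.extract_locus_reads([a], (100, 200)) == set()
        a.ref_start = 90  # straddles the locus start
        assert mapping.extract_locus_reads([a], (100, 200)) == {a.read_id}

    def test_locus_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            mapping.extract_locus_reads([], (100, 200), ref_len=150)

    def test_brute_force_equivalence_1000(self):
        """filter_alignments and extract_locus_reads agree exactly with
        exhaustive scans on 1,000 random alignments."""
        rng = np.random.default_rng(42)
        alns = _random_alignments(rng, 1000)
        got = mapping.filter_alignments(alns)
        expected = [a for a in alns
                    if a.mapq >= 30 and a.category == "primary"]
        assert got == expected
        locus = (4000, 6000)
        got_ids = mapping.extract_locus_reads(got, locus)
        brute = set()
        for a in got:
            overlap = min(a.ref_end, locus[1]) - max(a.ref_start, locus[0])
            inside = locus[0] <= a.ref_start and a.ref_end <= locus[1]
            if overlap >= 1 and not inside:
                brute.add(a.read_id)
        assert got_ids == brute

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    def test_filter_property(self, seed, q):
        rng = np.random.default_rng(seed)
        alns = _random_alignments(rng, 50)
        got = mapping.filter_alignments(alns, min_mapq=q,
                                        drop_categories={"secondary"})
        assert got == [a for a in alns
                       if a.mapq >= q and a.category != "secondary"]


class TestSamOutput:
    def test_sam_parses_with_pysam(self, ref, index, tmp_path):
        pysam = pytest.importorskip("pysam")
        reads = {"a": ref[2000:4000], "b": util.revcomp(ref[5000:7000]),
                 "junk": "ACGT" * 100}
        alns = []
        for rid, seq in reads.items():
            alns.extend(mapping.map_read(rid, seq, index, ref))
        path = tmp_path / "out.sam"
        mapping.write_sam(path, alns, "ref", len(ref), reads)
        seen = {}
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                seen[rec.query_name] = rec
                if not rec.is_unmapped:
                    assert rec.mapping_quality >= 0
                    assert rec.infer_read_length() == len(reads[rec.query_name])
        assert seen["junk"].is_unmapped
        assert seen["b"].is_reverse
        assert seen["a"].reference_start == 2000
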