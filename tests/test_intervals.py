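"""Interval algebra: normalization, shores, promoters, 5'-bodies, backbone.

Each operation is checked against a brute-force per-base membership oracle
on toy genomes, as the canonical independent reference.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from backbone_methylome.intervals import (
    GeneModel, GenomicInterval, MalformedIntervalError, RegionSet,
    build_backbone, five_prime_body_of, genome_regions, normalize,
    promoter_of, shore_of, union_all,
)


def coverage_set(rs: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean coverage — the brute-force oracle."""
    cov = np.zeros(length, dtype=bool)
    for s, e in rs.arrays(chrom):
        cov[s:e] = True
    return cov


def intervals_strategy():
    return st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 120)).map(
            lambda t: ("chr1", t[0], t[0] + t[1])),
        max_size=25)


class TestNormalize:
    def test_merges_overlapping(self):
        rs = RegionSet("x", [("chr1", 100, 200), ("chr1", 150, 300)])
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(100, 300)]

    def test_empty(self):
        assert normalize(RegionSet("x")).total_length() == 0

    def test_disjoint_unchanged(self):
        ivs = [("chr1", 10, 20), ("chr1", 30, 40), ("chr2", 5, 9)]
        rs = RegionSet("x", ivs)
        assert [(iv.chrom, iv.start, iv.end) for iv in rs.intervals()] == ivs

    def test_abutting_intervals_merge(self):
        rs = RegionSet("x", [("chr1", 10, 20), ("chr1", 20, 30)])
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(10, 30)]

    def test_malformed_rejected(self):
        with pytest.raises(MalformedIntervalError):
            RegionSet("x", [("chr1", 50, 50)])
        with pytest.raises(MalformedIntervalError):
            GenomicInterval("chr1", 10, 5)

    @settings(deadline=None, max_examples=50)
    @given(intervals_strategy())
    def test_matches_per_base_oracle_and_is_idempotent(self, ivs):
        rs = RegionSet("x", ivs)
        oracle = np.zeros(1100, dtype=bool)
        for _, s, e in ivs:
            oracle[s:e] = True
        assert np.array_equal(coverage_set(rs, "chr1", 1100), oracle)
        assert normalize(rs) == rs
        # merged representation has no overlapping/abutting neighbours
        arr = rs.arrays("chr1")
        assert (arr[1:, 0] > arr[:-1, 1]).all()

    @settings(deadline=None, max_examples=30)
    @given(intervals_strategy(), st.randoms())
    def test_order_independent(self, ivs, rnd):
        shuffled = list(ivs)
        rnd.shuffle(shuffled)
        assert RegionSet("x", ivs) == RegionSet("x", shuffled)


class TestShores:
    genome = {"chr1": 100_000}

    def test_flanks_both_sides(self):
        cgi = RegionSet("cgi", [("chr1", 10_000, 10_500)])
        shores = shore_of(cgi, self.genome)
        assert [(iv.start, iv.end) for iv in shores.intervals()] == [
            (8000, 10_000), (10_500, 12_500)]

    def test_clipped_at_chromosome_start(self):
        shores = shore_of(RegionSet("cgi", [("chr1", 500, 1000)]), self.genome)
        assert (shores.arrays("chr1")[0] == [0, 500]).all()

    def test_close_cgis_share_shore_bases_once_and_exclude_cgi(self):
        cgi = RegionSet("cgi", [("chr1", 10_000, 10_500), ("chr1", 11_500, 12_000)])
        shores = shore_of(cgi, self.genome)
        shore_cov = coverage_set(shores, "chr1", 100_000)
        cgi_cov = coverage_set(cgi, "chr1", 100_000)
        assert not (shore_cov & cgi_cov).any()
        # oracle: within 2 kb of a boundary, outside every CGI
        oracle = np.zeros(100_000, dtype=bool)
        oracle[8000:14_000] = True
        oracle &= ~cgi_cov
        assert np.array_equal(shore_cov, oracle)


class TestPromoterAndBody:
    genome = {"chr1": 50_000}

    def test_promoter_plus_strand(self):
        g = GeneModel("g", "chr1", 5000, 8000, "+")
        p = promoter_of(g, self.genome)
        assert (p.start, p.end) == (3500, 5000)

    def test_promoter_minus_strand(self):
        g = GeneModel("g", "chr1", 5000, 8000, "-")
        p = promoter_of(g, self.genome)
        assert (p.start, p.end) == (8000, 9500)

    def test_promoter_clipped_at_zero(self):
        g = GeneModel("g", "chr1", 1000, 4000, "+")
        p = promoter_of(g, self.genome)
        assert (p.start, p.end) == (0, 1000)

    def test_strandless_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 5000, 8000, ".")

    def test_five_prime_body(self):
        g = GeneModel("g", "chr1", 5000, 8000, "+")
        b = five_prime_body_of(g)
        assert (b.start, b.end) == (5000, 5300)
        g = GeneModel("g", "chr1", 5000, 8000, "-")
        b = five_prime_body_of(g)
        assert (b.start, b.end) == (7700, 8000)

    def test_minimal_gene_gives_one_base_body(self):
        g = GeneModel("g", "chr1", 100, 110, "+")
        b = five_prime_body_of(g)
        assert (b.start, b.end) == (100, 101)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(1000, 20_000), st.integers(10, 5000),
           st.sampled_from(["+", "-"]))
    def test_strand_symmetry(self, start, length, strand):
        """Reflecting coordinates and flipping strand reflects the regions."""
        L = 50_000
        end = start + length
        g = GeneModel("g", "chr1", start, end, strand)
        flipped = GeneModel("g", "chr1", L - end, L - start,
                            "-" if strand == "+" else "+")
        p, pf = promoter_of(g, self.genome), promoter_of(flipped, self.genome)
        assert (pf.start, pf.end) == (L - p.end, L - p.start)
        b, bf = five_prime_body_of(g), five_prime_body_of(flipped)
        assert (bf.start, bf.end) == (L - b.end, L - b.start)


class TestBackbone:
    def test_simple_complement(self):
        genome = {"chr1": 1000}
        bb = build_backbone(genome, [RegionSet("f", [("chr1", 100, 300)])],
                            RegionSet("repeat"))
        assert [(iv.start, iv.end) for iv in bb.intervals()] == [
            (0, 100), (300, 1000)]

    def test_empty_union_gives_whole_genome(self):
        genome = {"chr1": 500, "chr2": 300}
        bb = build_backbone(genome, [RegionSet("f")], RegionSet("r"))
        assert bb == genome_regions(genome)

    def test_full_union_gives_empty_backbone(self):
        genome = {"chr1": 500}
        bb = build_backbone(genome, [RegionSet("f", [("chr1", 0, 500)])],
                            RegionSet("r"))
        assert bb.total_length() == 0

    def test_random_genomes_match_per_base_complement(self):
        """Partition disjointness and coverage conservation, per-base."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            L = int(rng.integers(1000, 100_000))
            genome = {"chr1": L}
            sets = []
            for name in ("a", "b", "c"):
                n = int(rng.integers(0, 12))
                ivs = []
                for _ in range(n):
                    s = int(rng.integers(0, L - 1))
                    ivs.append(("chr1", s, min(L, s + int(rng.integers(1, L // 5 + 2)))))
                sets.append(RegionSet(name, ivs))
            bb = build_backbone(genome, sets[:-1], sets[-1])
            cov_union = np.zeros(L, dtype=bool)
            for rs in sets:
                cov_union |= coverage_set(rs, "chr1", L)
            assert np.array_equal(coverage_set(bb, "chr1", L), ~cov_union)
            union = union_all(sets)
            assert bb.total_length() + union.total_length() == L
            for rs in sets:
                assert bb.intersect(rs).total_length() == 0
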