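"""Quantiles, per-locus statistics, background sampling, GWAS filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trpoly.catalog import RepeatLocus
from trpoly.genotyping import CohortRow, GenotypeRow
from trpoly.stats import (
    LocusStats,
    SnpRecord,
    absolute_length,
    cohort_summary,
    filter_polymorphic_near_gwas,
    fraction_iqr_at_most,
    locus_stats,
    quantile,
    sample_background,
    snp_distance,
)


def brute_quantile(values, q):
    """Direct interpolation between order statistics: h = (n-1) q."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestQuantile:
    @pytest.mark.parametrize("values,q,expected", [
        ([0, 1, 2, 3], 0.25, 0.75),
        ([5], 0.1, 5.0),
        ([5], 0.9, 5.0),
        ([1, 1, 2, 3, 11], 0.75, 3.0),
    ])
    def test_hand_computed_examples(self, values, q, expected):
        assert quantile(values, q) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile([], 0.5)

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            values = rng.integers(-50, 51, size=n).tolist()
            q = float(rng.random())
            assert quantile(values, q) == pytest.approx(brute_quantile(values, q))


ATXN3 = RepeatLocus(chrom="chr14", start=92071010, end=92071040, unit="CAG",
                    gene="ATXN3", region="coding")
GLS = RepeatLocus(chrom="chr2", start=190880868, end=190880920, unit="GCA",
                  gene="GLS", region="utr5")


class TestLocusStats:
    def test_atxn3_style_quartile_lengths(self):
        # pooled deltas constructed so Q1 = 1 and Q3 = 11 exactly
        deltas = [1, 1, 1, 8, 8, 11, 11, 11, 11]
        s = locus_stats(deltas, ATXN3)
        assert s.q1 == 1.0 and s.q3 == 11.0
        assert s.q1_len == 33 and s.q3_len == 63
        assert s.iqr == 10.0

    def test_gls_style_fractional_quartiles(self):
        # sorted deltas with n=8: Q1 = x1 + 0.75(x2-x1), Q3 = x5 + 0.25(x6-x5)
        deltas = [-9, -8, -8, -6, -3, -2, 1, 2]
        s = locus_stats(deltas, GLS)
        assert s.q1 == -8.0 and s.q3 == -1.25
        assert s.iqr == 6.75
        assert s.q3_len == 48  # floor(52 - 3.75)

    def test_monomorphic_locus(self):
        s = locus_stats([0] * 10, ATXN3)
        assert s.iqr == 0.0 and s.mean_len == ATXN3.ref_span

    def test_empty_pool_is_undetected(self):
        s = locus_stats([], ATXN3)
        assert not s.detected and s.mean_delta is None and s.iqr is None

    def test_single_read_degenerate_quantiles(self):
        s = locus_stats([4], ATXN3)
        assert s.q1 == s.median_delta == s.q3 == 4.0
        assert s.low_coverage

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(-20, 30), min_size=1, max_size=60),
           st.integers(-5, 5))
    def test_iqr_shift_invariance_and_permutation(self, deltas, shift):
        s0 = locus_stats(deltas, ATXN3)
        s_shift = locus_stats([d + shift for d in deltas], ATXN3)
        assert s_shift.iqr == pytest.approx(s0.iqr)
        rng = np.random.default_rng(0)
        s_perm = locus_stats(list(rng.permutation(deltas)), ATXN3)
        assert s_perm.iqr == pytest.approx(s0.iqr)
        s_scaled = locus_stats([3 * d for d in deltas], ATXN3)
        assert s_scaled.iqr == pytest.approx(3 * s0.iqr)


def _cohort_row(locus, pooled_by_sample):
    samples = {
        label: GenotypeRow(locus=locus, forward=list(deltas))
        for label, deltas in pooled_by_sample.items()
    }
    return CohortRow(locus=locus, samples=samples)


class TestCohortSummary:
    def test_detection_rate_counts_loci_with_reads(self):
        l2 = RepeatLocus(chrom="chr2", start=100, end=130, unit="GGC")
        l3 = RepeatLocus(chrom="chr3", start=100, end=150, unit="AAAAT")
        rows = [
            _cohort_row(ATXN3, {"a": [0, 1], "b": [2]}),
            _cohort_row(l2, {"a": [], "b": [0]}),
            _cohort_row(l3, {"a": [], "b": []}),
        ]
        summary = cohort_summary(rows)
        assert len(summary.detected) == 2
        assert summary.detection_rate == pytest.approx(2 / 3)
        assert summary.per_sample_detection["a"] == pytest.approx(1 / 3)
        assert summary.per_sample_detection["b"] == pytest.approx(2 / 3)


class TestFractionIqr:
    def test_direct_count(self):
        stats = [
            locus_stats([0] * 4, ATXN3),                 # iqr 0
            locus_stats([0, 0, 1, 1], ATXN3),            # iqr 1
            locus_stats([0, 0, 2, 2], ATXN3),            # iqr 2
            locus_stats([0, 0, 3, 3], ATXN3),            # iqr 3
        ]
        assert fraction_iqr_at_most(stats, 2) == pytest.approx(0.75)
        assert fraction_iqr_at_most(stats, -1) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_iqr_at_most([], 2)


def _stats_pool(n, cls="CAG", region="coding", iqr_high=False, chrom="chr1"):
    pool = []
    for i in range(n):
        locus = RepeatLocus(chrom=chrom, start=1000 * (i + 1),
                            end=1000 * (i + 1) + 30, unit=cls, region=region)
        deltas = [0, 0, 8, 8] if iqr_high else [0, 0, 0, 0]
        pool.append(locus_stats(deltas, locus))
    return pool


class TestSampleBackground:
    def test_sets_match_class_region_and_exclusion(self):
        pool = _stats_pool(100)
        exclude = [pool[i].locus for i in range(12)]
        sets = sample_background(pool, "CAG", "coding", n=12, n_sets=10,
                                 exclude=exclude, seed=5)
        assert len(sets) == 10 and all(len(s) == 12 for s in sets)
        excluded_keys = {l.key for l in exclude}
        for s in sets:
            assert all(x.locus.key not in excluded_keys for x in s)

    def test_same_seed_reproduces(self):
        pool = _stats_pool(50)
        a = sample_background(pool, "CAG", "coding", n=10, n_sets=3, seed=9)
        b = sample_background(pool, "CAG", "coding", n=10, n_sets=3, seed=9)
        assert [[x.locus.key for x in s] for s in a] == \
               [[x.locus.key for x in s] for s in b]

    def test_exhaustive_pool_returns_the_single_set(self):
        pool = _stats_pool(5)
        sets = sample_background(pool, "CAG", "coding", n=5, n_sets=4, seed=1)
        keys = {frozenset(x.locus.key for x in s) for s in sets}
        assert len(keys) == 1

    def test_pool_too_small_reports_size(self):
        pool = _stats_pool(3)
        with pytest.raises(ValueError, match="3 matching"):
            sample_background(pool, "CAG", "coding", n=10)


class TestGwasFilter:
    def test_distance_arithmetic(self):
        locus = RepeatLocus(chrom="chr1", start=1000, end=1030, unit="CAG")
        assert snp_distance(locus, SnpRecord("chr1", 1010)) == 0
        assert snp_distance(locus, SnpRecord("chr1", 901)) == 99
        assert snp_distance(locus, SnpRecord("chr1", 900)) == 100
        assert snp_distance(locus, SnpRecord("chr1", 1128)) == 99
        assert snp_distance(locus, SnpRecord("chr2", 1010)) is None

    def test_threshold_boundaries(self):
        high = locus_stats([0, 0, 0, 8, 8, 8], ATXN3)          # iqr 8 -> eligible
        low = locus_stats([0, 0, 0, 4, 4, 4],                  # iqr 4.9-ish
                          RepeatLocus(chrom="chr14", start=500, end=530, unit="CAG"))
        inside = SnpRecord("chr14", 92071015, rsid="rs_in")
        near = SnpRecord("chr14", 92071010 - 99, rsid="rs_99")
        far = SnpRecord("chr14", 92071010 - 100, rsid="rs_100")
        hits = filter_polymorphic_near_gwas([high, low], [inside, near, far],
                                            min_iqr=5, max_dist=100)
        rsids = sorted(snp.rsid for _, snp, _ in hits)
        assert rsids == ["rs_99", "rs_in"]
        assert all(s.locus.gene == "ATXN3" for s, _, _ in hits)


class TestAbsoluteLength:
    @pytest.mark.parametrize("span,unit_len,dq,expected", [
        (30, 3, 11.0, 63),    # long CAG expansion quartile
        (60, 3, 11.0, 93),
        (70, 5, 6.0, 100),
        (63, 3, -3.0, 54),
        (52, 3, -1.25, 48),   # fractional quartile floors
    ])
    def test_examples(self, span, unit_len, dq, expected):
        unit = {3: "CAG", 5: "AAAAT"}[unit_len]
        locus = RepeatLocus(chrom="chr1", start=0, end=span, unit=unit)
        assert absolute_length(locus, dq) == expected
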