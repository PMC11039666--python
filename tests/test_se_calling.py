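"""SE calling: promoter exclusion, stitching, scoring, tangent cutoff."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sewaves.io_formats import CoverageMap, GenomicInterval, GeneRecord, Peak
from sewaves.se_calling import (
    SECallConfig,
    assign_genes,
    exclude_promoter_peaks,
    find_se_cutoff,
    mask_amplified,
    rpm_normalize,
    rpmpr_normalize,
    score_stitched,
    stitch_peaks,
)


def _peak(chrom, start, end, signal=1.0):
    return Peak(interval=GenomicInterval(chrom, start, end), signal=signal)


def _gene(gene_id, chrom, tss, is_tf=False):
    return GeneRecord(gene_id, gene_id.upper(), GenomicInterval(chrom, tss, tss + 1), is_tf)


# ---------------------------------------------------------------------------
# Promoter exclusion
# ---------------------------------------------------------------------------


class TestPromoterExclusion:
    def test_midpoint_within_window_is_excluded(self):
        # midpoint 1200, TSS 2000, window 2000 -> distance 800, excluded
        kept = exclude_promoter_peaks(
            [_peak("chr1", 1000, 1400)], [_gene("g", "chr1", 2000)], window=2000
        )
        assert kept == []

    def test_no_genes_keeps_everything(self):
        peaks = [_peak("chr1", 0, 100), _peak("chr1", 500, 600)]
        assert exclude_promoter_peaks(peaks, [], window=2000) == peaks

    def test_closed_boundary_and_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        genes = [_gene(f"g{i}", "chr1", int(t)) for i, t in
                 enumerate(np.sort(rng.integers(0, 100_000, 30)))]
        peaks = []
        for _ in range(300):
            s = int(rng.integers(0, 100_000))
            peaks.append(_peak("chr1", s, s + int(rng.integers(1, 500))))
        # a peak whose midpoint sits exactly at tss + window must go
        window = 1000
        tss = genes[0].tss.start
        peaks.append(_peak("chr1", tss + window - 50, tss + window + 50))
        kept = exclude_promoter_peaks(peaks, genes, window)
        brute = [
            p for p in peaks
            if all(abs(p.interval.midpoint - g.tss.start) > window for g in genes)
        ]
        assert kept == brute
        assert peaks[-1] not in kept


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------


def brute_force_stitch(peaks, distance):
    """Independent oracle: transitive closure by pairwise union-find."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    out = []
    for members in groups.values():
        chrom = members[0].interval.chrom
        out.append(
            (chrom, min(p.interval.start for p in members),
             max(p.interval.end for p in members), len(members))
        )
    return sorted(out)


class TestStitching:
    def test_gap_below_distance_merges(self):
        regions = stitch_peaks([_peak("chr1", 0, 1000), _peak("chr1", 5000, 6000)], 12_500)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 6000)
        assert len(regions[0].constituents) == 2

    def test_single_peak_identity(self):
        (r,) = stitch_peaks([_peak("chr1", 10, 20)], 12_500)
        assert r.interval == GenomicInterval("chr1", 10, 20)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        peaks = []
        for _ in range(int(rng.integers(1, 200))):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 200_000))
            peaks.append(_peak(chrom, s, s + int(rng.integers(1, 3000))))
        distance = int(rng.integers(0, 20_000))
        got = stitch_peaks(peaks, distance)
        assert sorted(
            (r.interval.chrom, r.interval.start, r.interval.end, len(r.constituents))
            for r in got
        ) == brute_force_stitch(peaks, distance)
        # constituent multiset conserved
        assert sorted(id(p) for r in got for p in r.constituents) == sorted(
            id(p) for p in peaks
        )

    def test_idempotent_and_gaps_exceed_distance(self):
        rng = np.random.default_rng(11)
        peaks = [_peak("chr1", int(s), int(s) + 100)
                 for s in np.sort(rng.integers(0, 500_000, 100))]
        regions = stitch_peaks(peaks, 5000)
        merged_again = stitch_peaks(
            [Peak(interval=r.interval) for r in regions], 5000
        )
        assert [r.interval for r in merged_again] == [r.interval for r in regions]
        for a, b in zip(regions, regions[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert b.interval.start - a.interval.end > 5000


# ---------------------------------------------------------------------------
# Scoring and cutoff
# ---------------------------------------------------------------------------


class TestScoring:
    def _cov(self, rows):
        return CoverageMap.from_records(rows)

    def test_input_subtraction_and_floor(self):
        treat = self._cov([("chr1", 0, 100, 5.0)])  # sum 500
        ctrl = self._cov([("chr1", 0, 100, 1.0)])  # sum 100
        heavy_ctrl = self._cov([("chr1", 0, 100, 9.0)])
        regions = stitch_peaks([_peak("chr1", 0, 100)], 0)
        (r,) = score_stitched(regions, treat, ctrl)
        assert r.load == 400.0
        (r,) = score_stitched(regions, treat, heavy_ctrl)
        assert r.load == 0.0  # floored
        (r,) = score_stitched(regions, treat, None)
        assert r.load == 500.0

    def test_rank_descends_with_load(self):
        peaks = [_peak("chr1", i * 10_000, i * 10_000 + 100) for i in range(5)]
        treat = self._cov([("chr1", i * 10_000, i * 10_000 + 100, float(i + 1))
                           for i in range(5)])
        ranked = score_stitched(stitch_peaks(peaks, 0), treat, None)
        loads = [r.load for r in ranked]
        assert loads == sorted(loads, reverse=True)
        assert [r.rank for r in ranked] == [1, 2, 3, 4, 5]


def oracle_cutoff(loads):
    """Exhaustive oracle: evaluate x - y at every index of the scaled
    ascending curve, keep the *last* maximizing index."""
    y = sorted(float(v) for v in loads)
    n = len(y)
    ymax = y[-1]
    best_idx, best_val = 0, -float("inf")
    for i in range(n):
        val = i / (n - 1) - y[i] / ymax
        if val >= best_val:
            best_idx, best_val = i, val
    return y[best_idx]


class TestCutoff:
    def test_single_outlier(self):
        cutoff, flags = find_se_cutoff([1, 2, 3, 4, 100])
        assert cutoff == 4
        assert list(flags) == [False, False, False, False, True]

    def test_two_supers_above_plateau(self):
        cutoff, flags = find_se_cutoff([1, 1, 1, 1, 1, 50, 60])
        assert cutoff == 1
        assert sum(flags) == 2

    def test_flat_curve_flags_nothing(self):
        _, flags = find_se_cutoff([7.0] * 10)
        assert not flags.any()

    def test_too_few_or_all_zero_errors(self):
        with pytest.raises(ValueError):
            find_se_cutoff([1, 2])
        with pytest.raises(ValueError):
            find_se_cutoff([0, 0, 0])

    def test_matches_exhaustive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(3, 2000))
            loads = rng.gamma(0.5, 100, n)
            loads[rng.integers(0, n)] *= 50  # ensure some spread
            cutoff, flags = find_se_cutoff(loads)
            assert cutoff == pytest.approx(oracle_cutoff(loads))
            assert list(flags) == [v > cutoff for v in loads]

    def test_raising_a_load_never_lowers_its_rank(self):
        rng = np.random.default_rng(8)
        loads = list(rng.gamma(1, 100, 50))
        order = np.argsort(np.argsort([-v for v in loads]))
        i = 17
        loads2 = list(loads)
        loads2[i] *= 3
        order2 = np.argsort(np.argsort([-v for v in loads2]))
        assert order2[i] <= order[i]


class TestAmplificationMask:
    def _regions(self, loads):
        regions = stitch_peaks(
            [_peak("chr1", i * 100_000, i * 100_000 + 100) for i in range(len(loads))], 0
        )
        for r, load in zip(regions, loads):
            r.load = load
        return regions

    def test_amplicon_excluded_from_fit_but_still_flagged(self):
        regions = self._regions([1, 2, 3, 4, 100, 1000])
        amplicon = [GenomicInterval("chr1", 500_000, 500_200)]  # covers the 1000 region
        cutoff_masked, fit, masked = mask_amplified(regions, amplicon)
        assert [r.load for r in masked] == [1000]
        assert regions[5].is_super  # flagged against the fitted cutoff
        cutoff_unmasked, _ = find_se_cutoff([r.load for r in regions])
        # without masking the amplicon compresses the curve: higher cutoff
        assert cutoff_masked < cutoff_unmasked
        assert cutoff_masked == pytest.approx(oracle_cutoff([1, 2, 3, 4, 100]))

    def test_empty_mask_is_a_no_op(self):
        regions = self._regions([1, 2, 3, 4, 100])
        cutoff, fit, masked = mask_amplified(regions, [])
        assert masked == []
        assert cutoff == find_se_cutoff([1, 2, 3, 4, 100])[0]

    def test_masking_everything_errors(self):
        regions = self._regions([1, 2, 3])
        with pytest.raises(ValueError, match="no regions left"):
            mask_amplified(regions, [GenomicInterval("chr1", 0, 10**7)])


# ---------------------------------------------------------------------------
# Gene assignment and normalization
# ---------------------------------------------------------------------------


class TestGeneAssignment:
    def test_window_semantics(self):
        (se,) = stitch_peaks([_peak("chr1", 100_000, 120_000)], 0)
        inside = _gene("near", "chr1", 160_000)
        outside = _gene("far", "chr1", 171_001)
        pairs = assign_genes([se], [inside, outside], window=50_000)
        assert [(g.gene_id, d) for _, g, d in pairs] == [("near", 40_000)]

    def test_every_qualifying_gene_is_linked(self):
        (se,) = stitch_peaks([_peak("chr1", 100_000, 120_000)], 0)
        genes = [
            _gene("a", "chr1", 110_000),  # inside -> distance 0
            _gene("b", "chr1", 130_000),
            _gene("c", "chr1", 60_000),
        ]
        pairs = assign_genes([se], genes, window=50_000)
        assert sorted((g.gene_id, d) for _, g, d in pairs) == [
            ("a", 0), ("b", 10_000), ("c", 40_000),
        ]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        ses = stitch_peaks(
            [_peak("chr1", int(s), int(s) + 5000)
             for s in rng.integers(0, 10**6, 20) * 1], 0
        )
        genes = [_gene(f"g{i}", "chr1", int(t)) for i, t in
                 enumerate(rng.integers(0, 10**6, 100))]
        window = 50_000
        got = {(se.interval.start, g.gene_id) for se, g, _ in assign_genes(ses, genes, window)}
        brute = set()
        for se in ses:
            for g in genes:
                t = g.tss.start
                if se.interval.start <= t < se.interval.end:
                    d = 0
                else:
                    d = min(abs(t - se.interval.start), abs(t - se.interval.end))
                if d <= window:
                    brute.add((se.interval.start, g.gene_id))
        assert got == brute


class TestNormalization:
    def test_rpm_unit_and_arithmetic(self):
        assert rpm_normalize(1, 10**6) == 1.0
        assert rpm_normalize(250, 5e7) == 5.0
        np.testing.assert_array_equal(rpm_normalize([0, 0], 100), [0.0, 0.0])

    def test_rpmpr_and_zero_denominators(self):
        assert rpmpr_normalize(100, 2e6) == 50.0
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)
        with pytest.raises(ValueError):
            rpmpr_normalize(1, 0)
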