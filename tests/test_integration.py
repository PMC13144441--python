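"""Signal matrices vs per-base references, bound-set ranking, LFC comparison."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tefoot import (
    SignalTrack,
    compare_lfc_groups,
    genes_near_insertions,
    matrix_reference_point,
    matrix_scale_regions,
    top_quartile_bound,
)
from tefoot.integration import BindingMatrix

from _oracles import (
    reference_reference_point_row,
    reference_scale_regions_row,
    welch_t,
)


def _random_track(seed, chrom="chr1", n=200, span=50_000):
    rng = np.random.default_rng(seed)
    edges = np.sort(rng.choice(np.arange(1, span), size=2 * n, replace=False))
    starts, ends = edges[0::2], edges[1::2]
    values = rng.gamma(2.0, 3.0, size=n)
    keep = rng.random(n) < 0.8  # leave gaps
    return SignalTrack({chrom: (starts[keep], ends[keep], values[keep])})


def _constant_track(value, span=50_000):
    return SignalTrack({"chr1": (np.array([0]), np.array([span]), np.array([value]))})


class TestScaleRegions:
    def test_constant_track(self):
        iv = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [5000, 9000, 20_000],
                           "end": [5400, 9300, 20_350], "strand": ["+", "-", "+"]})
        m = matrix_scale_regions(_constant_track(5.0), iv, 10, 200, 4)
        np.testing.assert_allclose(m.values, 5.0)

    def test_body_only_signal_and_strand_mirror(self):
        track = SignalTrack({"chr1": (np.array([1000]), np.array([1400]),
                                      np.array([10.0]))})
        iv = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1000, 1000],
                           "end": [1400, 1400], "strand": ["+", "-"],
                           "name": ["p", "m"]})
        m = matrix_scale_regions(track, iv, 8, 400, 4)
        rows = {lab: row for lab, row in zip(m.row_labels, m.values)}
        np.testing.assert_allclose(rows["p"][4:12], 10.0)
        np.testing.assert_allclose(rows["p"][:4], 0.0)
        np.testing.assert_allclose(rows["m"], rows["p"][::-1])

    def test_matches_per_base_reference(self):
        track = _random_track(21)
        rng = np.random.default_rng(22)
        starts = rng.integers(2000, 40_000, size=20)
        lengths = rng.integers(37, 900, size=20)
        iv = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + lengths,
            "strand": np.where(rng.random(20) < 0.5, "+", "-"),
            "name": [f"iv{i}" for i in range(20)],
        })
        m = matrix_scale_regions(track, iv, body_bins=13, flank_bp=500, flank_bins=5)
        rows = {lab: row for lab, row in zip(m.row_labels, m.values)}
        for rec in iv.itertuples(index=False):
            ref = reference_scale_regions_row(track, "chr1", rec.start, rec.end,
                                              rec.strand, 13, 500, 5)
            np.testing.assert_allclose(rows[rec.name], ref, atol=1e-9)


class TestReferencePoint:
    def test_constant_track(self):
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        m = matrix_reference_point(_constant_track(3.0), pts, 1000, 1000, 10)
        np.testing.assert_allclose(m.values, 3.0)

    def test_delta_signal_central_bin(self):
        track = SignalTrack({"chr1": (np.array([10_000]), np.array([10_001]),
                                      np.array([50.0]))})
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        m = matrix_reference_point(track, pts, 1000, 1000, 10)
        (row,) = m.values
        assert row[100] > 0 and np.count_nonzero(row) == 1

    def test_bin_divisibility_enforced(self):
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "strand": ["+"]})
        with pytest.raises(ValueError, match="divide"):
            matrix_reference_point(_constant_track(1.0), pts, 1000, 1000, 7)

    def test_edge_clipping_flagged_and_zero_filled(self):
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [300], "strand": ["+"]})
        m = matrix_reference_point(_constant_track(2.0), pts, 1000, 1000, 10)
        assert m.edge_clipped[0]
        (row,) = m.values
        np.testing.assert_allclose(row[:70], 0.0)
        np.testing.assert_allclose(row[70:], 2.0)

    def test_matches_per_base_reference(self):
        track = _random_track(31)
        rng = np.random.default_rng(32)
        pts = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(1500, 45_000, size=15),
            "strand": np.where(rng.random(15) < 0.5, "+", "-"),
            "name": [f"p{i}" for i in range(15)],
        })
        m = matrix_reference_point(track, pts, 1000, 1000, 10)
        rows = {lab: row for lab, row in zip(m.row_labels, m.values)}
        for rec in pts.itertuples(index=False):
            ref = reference_reference_point_row(track, "chr1", rec.pos, rec.strand,
                                                1000, 1000, 10)
            np.testing.assert_allclose(rows[rec.name], ref, atol=1e-9)


class TestTopQuartile:
    def _matrix(self, sums):
        rows = np.array([[s] for s in sums], dtype=float)
        return BindingMatrix.from_rows(rows, [f"r{i}" for i in range(len(sums))])

    def test_eight_rows_top_two(self):
        m = self._matrix([1, 8, 3, 7, 2, 6, 4, 5])
        assert top_quartile_bound(m, 0.25) == ["r1", "r3"]

    def test_fraction_one_all_rows(self):
        m = self._matrix([3, 1, 2])
        assert set(top_quartile_bound(m, 1.0)) == {"r0", "r1", "r2"}

    def test_tie_break_input_order(self):
        m = self._matrix([5, 5, 5, 5, 5, 5, 5, 5])
        assert top_quartile_bound(m, 0.25) == ["r0", "r1"]

    def test_monotone_nesting(self):
        rng = np.random.default_rng(9)
        m = self._matrix(rng.random(23))
        prev = set()
        for frac in (0.1, 0.25, 0.5, 0.9, 1.0):
            cur = set(top_quartile_bound(m, frac))
            assert prev <= cur
            prev = cur

    def test_empty_matrix_raises(self):
        m = BindingMatrix.from_rows(np.zeros((0, 3)), [])
        with pytest.raises(ValueError, match="empty"):
            top_quartile_bound(m)


class TestGenesNearInsertions:
    INSERTS = pd.DataFrame({"chrom": ["chr1"], "start": [12_000], "end": [12_300]})

    def _genes(self, tss_list):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(tss_list))],
                             "chrom": "chr1", "tss": tss_list,
                             "lfc": np.zeros(len(tss_list))})

    def test_within_window_included(self):
        sub = genes_near_insertions(self._genes([5000]), self.INSERTS, 10_000)
        assert list(sub.gene) == ["g0"]

    def test_boundary_inclusive_at_exactly_10kb(self):
        genes = self._genes([2000, 1999])  # distances 10_000 and 10_001
        sub = genes_near_insertions(genes, self.INSERTS, 10_000)
        assert list(sub.gene) == ["g0"]

    def test_tss_inside_distance_zero(self):
        sub = genes_near_insertions(self._genes([12_100]), self.INSERTS, 0)
        assert list(sub.gene) == ["g0"]

    def test_monotone_in_window(self):
        rng = np.random.default_rng(13)
        genes = self._genes(rng.integers(0, 60_000, size=40))
        prev = set()
        for window in (0, 1000, 5000, 20_000, 60_000):
            cur = set(genes_near_insertions(genes, self.INSERTS, window).gene)
            assert prev <= cur
            prev = cur


class TestCompareLfcGroups:
    def test_identical_groups(self):
        res = compare_lfc_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_separated_means(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1e-3, size=4)
        b = 1.0 + rng.normal(0, 1e-3, size=4)
        assert compare_lfc_groups(a, b).pvalue < 0.01

    def test_matches_closed_form_welch(self):
        a = [-1.2, 0.3, 0.8, -0.5, 1.1]
        b = [0.4, 0.9, 1.5, 0.2, -0.3, 1.8, 0.7]
        res = compare_lfc_groups(a, b, welch=True)
        t, dof, p = welch_t(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.dof == pytest.approx(dof)
        assert res.pvalue == pytest.approx(p)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            compare_lfc_groups([1.0], [1.0, 2.0])
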