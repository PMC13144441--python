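"""Binding-signal aggregation over TE insertions and TSSs, and LFC comparison.

Mirrors the deeptools computeMatrix geometries on textual bedGraph tracks:
``scale-regions`` resamples each interval body to a fixed number of bins
with fixed-width flanks, ``reference-point`` takes a fixed window around a
point (a TSS). Bin values are length-weighted mean coverage, gaps count as
zero coverage, and minus-strand rows are reversed so bins read 5'->3'.

Insertions are classified "bound" when they rank in the top quartile of
matrix row sums; genes whose TSS lies within 10 kb of a bound insertion are
compared against genes near any insertion by a two-sided unpaired t-test on
their log2 fold changes (Welch by default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignalTrack",
    "BindingMatrix",
    "TTestResult",
    "matrix_scale_regions",
    "matrix_reference_point",
    "top_quartile_bound",
    "genes_near_insertions",
    "compare_lfc_groups",
]


@dataclass
class SignalTrack:
    """Sparse per-chromosome step coverage (bedGraph semantics, gaps = 0)."""

    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self):
        clean = {}
        for chrom, (starts, ends, values) in self.chroms.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: intervals must have end > start")
            if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping intervals")
            if (values < 0).any():
                raise ValueError(f"{chrom}: negative signal values")
            clean[chrom] = (starts, ends, values)
        self.chroms = clean

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        data: dict[str, list[list]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end, value = line.split()[:4]
                data.setdefault(chrom, []).append((int(start), int(end), float(value)))
        chroms = {
            c: (np.array([r[0] for r in rows]), np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]))
            for c, rows in data.items()
        }
        return cls(chroms)

    def mean_over(self, chrom: str, start: float, end: float) -> float:
        """Length-weighted mean coverage over [start, end); gaps count as 0."""
        if end <= start:
            raise ValueError("end must be > start")
        if chrom not in self.chroms:
            return 0.0
        starts, ends, values = self.chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        overlap = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        integral = float(np.sum(values[lo:hi] * np.clip(overlap, 0.0, None)))
        return integral / (end - start)

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        return np.array([
            self.mean_over(chrom, edges[i], edges[i + 1]) for i in range(len(edges) - 1)
        ])


@dataclass
class BindingMatrix:
    """Interval x bin signal summary, rows ordered by descending row sum."""

    values: np.ndarray            # sorted by descending row sum
    row_labels: list[str]         # in sorted order
    input_order: np.ndarray       # original index of each sorted row
    edge_clipped: np.ndarray = field(default=None)

    @classmethod
    def from_rows(cls, rows: np.ndarray, labels: Sequence[str],
                  clipped: np.ndarray | None = None) -> "BindingMatrix":
        rows = np.asarray(rows, dtype=np.float64)
        if rows.ndim != 2:
            raise ValueError("matrix must be 2-D")
        order = np.argsort(-rows.sum(axis=1), kind="stable")
        return cls(
            values=rows[order],
            row_labels=[labels[i] for i in order],
            input_order=order,
            edge_clipped=clipped[order] if clipped is not None else np.zeros(len(rows), bool),
        )

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.row_labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _interval_row(track: SignalTrack, chrom: str, start: int, end: int, strand: str,
                  body_bins: int, flank_bp: int, flank_bins: int) -> np.ndarray:
    up_edges = np.linspace(start - flank_bp, start, flank_bins + 1)
    body_edges = np.linspace(start, end, body_bins + 1)
    down_edges = np.linspace(end, end + flank_bp, flank_bins + 1)
    row = np.concatenate([
        track.binned_means(chrom, up_edges),
        track.binned_means(chrom, body_edges),
        track.binned_means(chrom, down_edges),
    ])
    if strand == "-":
        row = row[::-1]
    return row


def matrix_scale_regions(
    track: SignalTrack,
    intervals: pd.DataFrame,
    body_bins: int = 30,
    flank_bp: int = 1000,
    flank_bins: int = 10,
) -> BindingMatrix:
    """Body-resampled signal matrix over intervals (deeptools scale-regions).

    Each body is split into ``body_bins`` equal sub-intervals regardless of
    its length (shorter intervals get proportional-overlap bin values);
    flanks are fixed-width. Minus-strand rows are mirrored.
    """
    if body_bins < 1 or flank_bins < 1:
        raise ValueError("bins must be >= 1")
    if not len(intervals):
        raise ValueError("empty interval set")
    rows, labels = [], []
    for i, rec in enumerate(intervals.itertuples(index=False)):
        strand = getattr(rec, "strand", "+")
        rows.append(_interval_row(track, rec.chrom, rec.start, rec.end, strand,
                                  body_bins, flank_bp, flank_bins))
        labels.append(getattr(rec, "name", f"row{i}"))
    return BindingMatrix.from_rows(np.array(rows), labels)


def matrix_reference_point(
    track: SignalTrack,
    points: pd.DataFrame,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    bin_bp: int = 10,
) -> BindingMatrix:
    """Fixed-window signal matrix around reference points (e.g. TSSs).

    The window is ``[pos - upstream, pos + downstream)`` oriented 5'->3' by
    strand; ``bin_bp`` must divide the window. Bins that fall before the
    chromosome start are filled with 0 and the row is flagged as clipped.
    """
    window = upstream_bp + downstream_bp
    if window % bin_bp:
        raise ValueError("bin_bp must divide upstream_bp + downstream_bp")
    if not len(points):
        raise ValueError("empty point set")
    n_bins = window // bin_bp
    rows, labels, clipped = [], [], []
    for i, rec in enumerate(points.itertuples(index=False)):
        strand = getattr(rec, "strand", "+")
        pos = rec.pos
        edges = pos - upstream_bp + bin_bp * np.arange(n_bins + 1)
        row = np.zeros(n_bins)
        was_clipped = edges[0] < 0
        for b in range(n_bins):
            a, z = edges[b], edges[b + 1]
            if z <= 0:
                continue
            row[b] = track.mean_over(rec.chrom, max(a, 0), z) * (z - max(a, 0)) / bin_bp
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        labels.append(getattr(rec, "name", f"row{i}"))
        clipped.append(bool(was_clipped))
    return BindingMatrix.from_rows(np.array(rows), labels, np.array(clipped))


def top_quartile_bound(matrix: BindingMatrix, fraction: float = 0.25) -> list[str]:
    """Row labels of the top ``ceil(fraction * n)`` rows by row sum.

    Ties keep the original input order (stable ranking).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if matrix.n_rows == 0:
        raise ValueError("empty matrix")
    k = math.ceil(fraction * matrix.n_rows)
    return matrix.row_labels[:k]


def genes_near_insertions(
    genes: pd.DataFrame,
    insertions: pd.DataFrame,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Genes whose TSS lies within ``window_bp`` of any insertion interval.

    Distance is the gap to the half-open interval (0 if the TSS is inside);
    the boundary is inclusive, so a TSS at exactly ``window_bp`` is kept.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in insertions.groupby("chrom"):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        order = np.argsort(starts)
        by_chrom[chrom] = (starts[order], ends[order])
    keep = []
    for idx, rec in zip(genes.index, genes.itertuples(index=False)):
        spans = by_chrom.get(rec.chrom)
        if spans is None:
            continue
        starts, ends = spans
        tss = rec.tss
        dist = np.maximum(0, np.maximum(starts - tss, tss - (ends - 1)))
        if dist.min() <= window_bp:
            keep.append(idx)
    return genes.loc[keep]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: float
    pvalue: float


def compare_lfc_groups(
    lfc_bound: Sequence[float],
    lfc_all: Sequence[float],
    welch: bool = True,
) -> TTestResult:
    """Two-sided unpaired t-test between the two LFC groups.

    Welch (unequal variance) by default; ``welch=False`` gives the
    pooled-variance Student's test.
    """
    a = np.asarray(lfc_bound, dtype=np.float64)
    b = np.asarray(lfc_all, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate groups: zero variance in both")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
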