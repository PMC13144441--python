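"""Independent reference implementations used as oracles in the tests.

Everything here is deliberately written with plain Python loops, separate
from the vectorized library code paths, so each test compares two
independent routes to the same definition.
"""
from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- footprints

def reference_call_footprints(vector, library_size, window, flank, w_min, w_max,
                              d_min, c_min):
    """Exhaustive loop-based footprint caller (same rule as the library).

    Returns a list of (start, end, D) tuples numbered left to right.
    """
    pm = [v * 1e6 / library_size for v in vector]
    n = len(pm)
    h = window // 2
    s = [sum(pm[max(0, i - h):min(n, i + h + 1)]) /
         len(pm[max(0, i - h):min(n, i + h + 1)]) for i in range(n)]
    # local flank mean: +/- flank around i, excluding i
    local = []
    for i in range(n):
        vals = [s[j] for j in range(max(0, i - flank), min(n, i + flank + 1)) if j != i]
        local.append(sum(vals) / len(vals))
    mask = [s[i] < (1.0 - d_min) * local[i] for i in range(n)]
    runs = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < w_min / 2:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for a, b in merged:
        if not (w_min <= b - a <= w_max):
            continue
        left = s[max(0, a - flank):a]
        right = s[b:min(n, b + flank)]
        flank_vals = left + right
        if not flank_vals:
            continue
        m_flank = sum(flank_vals) / len(flank_vals)
        if m_flank < c_min:
            continue
        m_center = sum(s[a:b]) / (b - a)
        d = 0.0 if m_flank == 0 else (m_flank - m_center) / m_flank
        out.append((a, b, d))
    return out


# ------------------------------------------------------------ motif alignment

def _column_distance(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_force_align(query, target, min_overlap, search_rc=False):
    """Enumerate every offset (and orientation) with loops; return the best.

    Ties: smaller |offset|, then negative offset, then '+' strand.
    """
    uniform = (0.25, 0.25, 0.25, 0.25)
    candidates = [(query, "+")]
    if search_rc:
        rc = [[row[3 - b] for b in range(4)] for row in query[::-1]]
        candidates.append((rc, "-"))
    best = None
    for mat, strand in candidates:
        wq, wt = len(mat), len(target)
        for k in range(-(wq - min_overlap), wt - min_overlap + 1):
            total = 0.0
            for i in range(wq):
                j = i + k
                if 0 <= j < wt:
                    total += _column_distance(mat[i], target[j])
                else:
                    total += _column_distance(mat[i], uniform)
            d = total / wq
            key = (d, abs(k), 0 if k < 0 else 1, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, d, k, strand)
    return best[1], best[2], best[3]


# -------------------------------------------------------- per-base matrices

def dense_track(track, chrom, lo, hi):
    """Expand a SignalTrack chromosome to a dense per-base array over [lo, hi)."""
    dense = np.zeros(hi - lo)
    if chrom in track.chroms:
        starts, ends, values = track.chroms[chrom]
        for s, e, v in zip(starts, ends, values):
            a, b = max(s, lo), min(e, hi)
            if a < b:
                dense[a - lo:b - lo] = v
    return dense


def _bin_mean_dense(dense, lo, a, b):
    """Length-weighted mean over [a, b) of a per-base step function.

    Bases outside the dense window count as 0 coverage.
    """
    total = 0.0
    for i in range(math.floor(a), math.ceil(b)):
        frac = min(i + 1, b) - max(i, a)
        if frac <= 0:
            continue
        if 0 <= i - lo < len(dense):
            total += dense[i - lo] * frac
    return total / (b - a)


def reference_scale_regions_row(track, chrom, start, end, strand,
                                body_bins, flank_bp, flank_bins):
    lo = min(0, start - flank_bp)
    hi = end + flank_bp
    dense = dense_track(track, chrom, max(lo, 0), hi)
    row = []
    for b in range(flank_bins):
        a = start - flank_bp + b * flank_bp / flank_bins
        z = start - flank_bp + (b + 1) * flank_bp / flank_bins
        row.append(_bin_mean_dense(dense, max(lo, 0), a, z))
    width = (end - start) / body_bins
    for b in range(body_bins):
        row.append(_bin_mean_dense(dense, max(lo, 0), start + b * width,
                                   start + (b + 1) * width))
    for b in range(flank_bins):
        a = end + b * flank_bp / flank_bins
        z = end + (b + 1) * flank_bp / flank_bins
        row.append(_bin_mean_dense(dense, max(lo, 0), a, z))
    if strand == "-":
        row = row[::-1]
    return np.array(row)


def reference_reference_point_row(track, chrom, pos, strand,
                                  upstream_bp, downstream_bp, bin_bp):
    lo = max(pos - upstream_bp, 0)
    hi = pos + downstream_bp
    dense = dense_track(track, chrom, lo, hi) if hi > lo else np.zeros(0)
    n_bins = (upstream_bp + downstream_bp) // bin_bp
    row = []
    for b in range(n_bins):
        a = pos - upstream_bp + b * bin_bp
        z = a + bin_bp
        # bins before the chromosome start contribute 0 coverage
        row.append(_bin_mean_dense(dense, lo, max(a, 0), z) * (z - max(a, 0)) / bin_bp
                   if z > 0 else 0.0)
    if strand == "-":
        row = row[::-1]
    return np.array(row)


def welch_t(a, b):
    """Closed-form Welch t statistic, dof and two-sided p (loops + math)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), dof)
    return t, dof, p
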