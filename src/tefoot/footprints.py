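"""Footprint calling on consensus meta-profiles.

A TF footprint appears as a local depletion of Tn5 insertion frequency
relative to a higher signal in the flanking regions. This module turns that
qualitative picture into a reproducible statistic and caller:

* depletion score ``D = (m_flank - m_center) / m_flank`` where ``m_center``
  is the mean signal over the candidate interval and ``m_flank`` the mean
  over up to ``F`` positions on each side (``D = 0`` when ``m_flank = 0``);
* candidate positions are those whose smoothed value falls below
  ``(1 - d_min)`` times the local flank mean (the mean over the surrounding
  ``±F`` positions, excluding the position itself);
* maximal runs of candidate positions are merged across gaps shorter than
  ``w_min / 2``, filtered to widths in ``[w_min, w_max]`` and to flank
  signal at least ``c_min`` per million, scored, and numbered left to right.

Calls are made per stage and unified across stages by reciprocal interval
overlap, after which a footprint's stage-specificity label is the set of
stages where its depletion score reaches ``d_min``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .profiles import MetaProfile, smooth_profile
from .repeats import ConsensusLibrary

__all__ = [
    "FootprintCallParams",
    "Footprint",
    "depletion_score",
    "depletion_stats",
    "call_footprints",
    "classify_stages",
    "unify_and_classify",
    "extract_footprint_sequence",
]


@dataclass(frozen=True)
class FootprintCallParams:
    """Caller parameters. Defaults suit 6-30 bp TF footprints on per-million profiles."""

    window: int = 3          # smoothing window (odd, bp)
    flank: int = 25          # flank width F (bp)
    w_min: int = 6           # minimum footprint width (bp)
    w_max: int = 30          # maximum footprint width (bp)
    d_min: float = 0.3       # depletion threshold
    c_min: float = 0.5       # minimum flank signal (per million)

    def __post_init__(self):
        if min(self.window, self.flank, self.w_min, self.w_max) < 1:
            raise ValueError("window, flank, w_min, w_max must be positive")
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")
        if not (0 < self.d_min <= 1) or self.c_min < 0:
            raise ValueError("d_min in (0,1], c_min >= 0 required")


@dataclass
class Footprint:
    """A consensus-coordinate interval with per-stage depletion scores."""

    family: str
    start: int
    end: int
    index: int = 0
    scores: dict[str, float] = field(default_factory=dict)   # stage -> D
    present: dict[str, bool] = field(default_factory=dict)   # stage -> D >= d_min
    flank_means: dict[str, float] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> frozenset[str]:
        return frozenset(s for s, p in self.present.items() if p)

    @property
    def name(self) -> str:
        return f"{self.family}_fp{self.index}"


def depletion_stats(vector: np.ndarray, start: int, end: int, flank: int
                    ) -> tuple[float, float, float]:
    """Return (D, m_center, m_flank) for an interval on a profile vector."""
    vector = np.asarray(vector, dtype=np.float64)
    n = len(vector)
    if not (0 <= start < end <= n):
        raise ValueError(f"interval [{start},{end}) outside profile of length {n}")
    left = vector[max(0, start - flank):start]
    right = vector[end:min(n, end + flank)]
    if len(left) + len(right) == 0:
        raise ValueError("flanks are empty; interval spans the whole profile")
    m_center = float(vector[start:end].mean())
    m_flank = float(np.concatenate([left, right]).mean())
    if m_flank == 0.0:
        return 0.0, m_center, 0.0
    return (m_flank - m_center) / m_flank, m_center, m_flank


def depletion_score(vector: np.ndarray, start: int, end: int, flank: int) -> float:
    """Depletion D = (m_flank - m_center) / m_flank; 0 when m_flank is 0."""
    return depletion_stats(vector, start, end, flank)[0]


def _local_flank_means(smoothed: np.ndarray, flank: int) -> np.ndarray:
    """Mean over [i-F, i+F] excluding i, truncated at the profile edges."""
    n = len(smoothed)
    if n < 2:
        raise ValueError("profile too short for local flank means")
    cum = np.concatenate([[0.0], np.cumsum(smoothed)])
    idx = np.arange(n)
    lo = np.clip(idx - flank, 0, n)
    hi = np.clip(idx + flank + 1, 0, n)
    sums = cum[hi] - cum[lo]
    counts = hi - lo
    return (sums - smoothed) / (counts - 1)


def _candidate_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if not len(idx):
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_footprints(profile: MetaProfile, params: FootprintCallParams | None = None
                    ) -> list[Footprint]:
    """Call footprints on one stage's meta-profile (see module docstring)."""
    params = params or FootprintCallParams()
    smoothed = smooth_profile(profile.per_million, params.window)
    if not len(smoothed):
        raise ValueError("empty profile")
    local = _local_flank_means(smoothed, params.flank)
    mask = smoothed < (1.0 - params.d_min) * local
    runs = _candidate_runs(mask)
    # merge runs separated by gaps shorter than w_min / 2
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < params.w_min / 2:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out: list[Footprint] = []
    for s, e in merged:
        if not (params.w_min <= e - s <= params.w_max):
            continue
        d, _, m_flank = depletion_stats(smoothed, s, e, params.flank)
        if m_flank < params.c_min:
            continue
        out.append(Footprint(profile.family, s, e,
                             scores={profile.stage: d},
                             present={profile.stage: d >= params.d_min},
                             flank_means={profile.stage: m_flank}))
    for i, fp in enumerate(out, start=1):
        fp.index = i
    return out


def classify_stages(scores: dict[str, float], d_min: float,
                    stages: list[str] | None = None) -> frozenset[str]:
    """Stage-specificity label: the set of stages with D >= d_min."""
    if stages is not None:
        missing = [s for s in stages if s not in scores]
        if missing:
            raise ValueError(f"missing depletion scores for stages {missing}")
    return frozenset(s for s, d in scores.items() if d >= d_min)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])


def unify_and_classify(profiles: dict[str, MetaProfile],
                       params: FootprintCallParams | None = None) -> list[Footprint]:
    """Call per stage, merge intervals across stages, classify stage-specificity.

    Intervals from different stages with >= 50% reciprocal overlap are merged
    into their union; per-stage depletion scores are then recomputed on the
    unified interval for every stage and presence flags set by ``d_min``.
    """
    params = params or FootprintCallParams()
    if not profiles:
        raise ValueError("no profiles supplied")
    family = next(iter(profiles.values())).family
    intervals: list[tuple[int, int]] = []
    for stage, prof in profiles.items():
        if prof.family != family:
            raise ValueError("profiles must all belong to one family")
        intervals.extend((fp.start, fp.end) for fp in call_footprints(prof, params))
    intervals.sort()
    clusters: list[tuple[int, int]] = []
    for iv in intervals:
        if clusters and _reciprocal_overlap(clusters[-1], iv) >= 0.5:
            clusters[-1] = (min(clusters[-1][0], iv[0]), max(clusters[-1][1], iv[1]))
        else:
            clusters.append(iv)
    smoothed = {s: smooth_profile(p.per_million, params.window) for s, p in profiles.items()}
    out: list[Footprint] = []
    for i, (s, e) in enumerate(clusters, start=1):
        scores, flanks = {}, {}
        for stage, vec in smoothed.items():
            d, _, m_flank = depletion_stats(vec, s, e, params.flank)
            scores[stage] = d
            flanks[stage] = m_flank
        present = {stage: d >= params.d_min for stage, d in scores.items()}
        out.append(Footprint(family, s, e, index=i, scores=scores,
                             present=present, flank_means=flanks))
    return out


def extract_footprint_sequence(footprint: Footprint, library: ConsensusLibrary,
                               pad: int = 0) -> tuple[str, str]:
    """Consensus substring under the (padded) footprint, forward and reverse.

    Both strands are returned because a TF's motif may sit on either strand
    of the consensus. Padding is clipped to the consensus bounds.
    """
    consensus = library.sequence(footprint.family)
    start = max(0, footprint.start - pad)
    end = min(len(consensus), footprint.end + pad)
    fwd = consensus[start:end]
    return fwd, revcomp(fwd)
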