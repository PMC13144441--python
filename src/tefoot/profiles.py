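"""Tn5 insertion tracks and per-family meta-profiles in consensus coordinates.

A fragment pair of Tn5 cuts marks two single-base insertion events; the
pipeline quantifies those events inside intact copies of each TE family,
projects them onto the family consensus, and normalizes by genome-wide
library size to insertions per million.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .repeats import IntactSet

logger = logging.getLogger(__name__)

__all__ = [
    "InsertionTrack",
    "MetaProfile",
    "fragments_to_insertions",
    "read_fragments_bedpe",
    "write_fragments_bedpe",
    "build_meta_profile",
    "smooth_profile",
]


@dataclass
class InsertionTrack:
    """Single-base Tn5 cut events for one stage.

    ``positions`` maps chromosome -> sorted array of 0-based cut positions
    (with multiplicity). ``library_size`` is the genome-wide event total and
    is the per-million normalization denominator.
    """

    stage: str
    positions: dict[str, np.ndarray]
    library_size: int

    def __post_init__(self):
        n = sum(len(p) for p in self.positions.values())
        if self.library_size < n:
            raise ValueError("library_size must be >= number of stored events")
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) and pos.min() < 0:
                raise ValueError(f"{chrom}: negative cut positions")
            self.positions[chrom] = np.sort(pos)

    @property
    def n_events(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @classmethod
    def from_events(cls, stage: str, chroms: Iterable[str], pos: Iterable[int],
                    library_size: int | None = None) -> "InsertionTrack":
        df = pd.DataFrame({"chrom": list(chroms), "pos": list(pos)})
        grouped = {c: g["pos"].to_numpy(np.int64) for c, g in df.groupby("chrom")}
        if library_size is None:
            library_size = len(df)
        return cls(stage, grouped, library_size)

    @classmethod
    def from_bed(cls, path: str | Path, stage: str = "") -> "InsertionTrack":
        """Read a BED3(+strand) file of single-base cut events."""
        chroms, positions = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = line.split()
                chroms.append(f[0])
                positions.append(int(f[1]))
        return cls.from_events(stage, chroms, positions)

    def to_bed(self, path: str | Path, strands: Mapping[str, np.ndarray] | None = None) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.positions):
                st = strands.get(chrom) if strands else None
                for i, p in enumerate(self.positions[chrom]):
                    strand = st[i] if st is not None else "+"
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t0\t{strand}\n")


def fragments_to_insertions(
    fragments: pd.DataFrame,
    shift_plus: int = 4,
    shift_minus: int = 5,
    stage: str = "",
) -> InsertionTrack:
    """Convert fragments (chrom, start, end) to two cut events each.

    The plus-end cut is ``start + shift_plus``; the minus-end cut is
    ``end - 1 - shift_minus``. The (+4, -5) default is the standard ATAC
    convention for recovering Tn5 insertion centres from fragment ends.
    Records with ``end <= start`` are skipped (counted in a warning).
    """
    bad = fragments["end"] <= fragments["start"]
    if bad.any():
        logger.warning("skipping %d fragments with end <= start", int(bad.sum()))
        fragments = fragments[~bad]
    chroms = np.concatenate([fragments["chrom"].to_numpy()] * 2) if len(fragments) else np.array([])
    cuts = np.concatenate([
        fragments["start"].to_numpy(np.int64) + shift_plus,
        fragments["end"].to_numpy(np.int64) - 1 - shift_minus,
    ]) if len(fragments) else np.array([], dtype=np.int64)
    track = InsertionTrack.from_events(stage, chroms, cuts, library_size=2 * len(fragments))
    return track


def read_fragments_bedpe(path: str | Path) -> pd.DataFrame:
    """Read the BEDPE dialect written by the simulator.

    Each record's two blocks are the two cut bases; the fragment spans
    from the first block start to the second block end.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split()
            rows.append((f[0], int(f[1]), int(f[5])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_fragments_bedpe(fragments: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in fragments[["chrom", "start", "end"]].itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{chrom}\t{end - 1}\t{end}\t.\t0\t+\t-\n")


@dataclass
class MetaProfile:
    """Aggregated insertion-frequency vector for one family at one stage."""

    family: str
    stage: str
    raw: np.ndarray              # counts per consensus position
    n_copies: int
    library_size: int

    @property
    def per_million(self) -> np.ndarray:
        return self.raw * 1e6 / self.library_size

    def to_tsv(self, path: str | Path) -> None:
        pm = self.per_million
        with open(path, "w") as fh:
            fh.write("position\traw\tper_million\n")
            for i, (r, p) in enumerate(zip(self.raw, pm)):
                fh.write(f"{i}\t{r:.0f}\t{p:.6f}\n")

    def to_bedgraph(self, path: str | Path) -> None:
        """Per-million signal in consensus coordinates (chrom = family name)."""
        pm = self.per_million
        with open(path, "w") as fh:
            for i, v in enumerate(pm):
                fh.write(f"{self.family}\t{i}\t{i + 1}\t{v:.6f}\n")


def build_meta_profile(track: InsertionTrack, intact: IntactSet, family: str) -> MetaProfile:
    """Project every in-element cut of a family onto consensus coordinates.

    A cut belongs to a copy iff its position is in ``[start, end)``; minus
    strand copies contribute reflected positions. The result is normalized
    per million genome-wide library insertions.
    """
    if family not in intact.copies or not intact.copies[family]:
        raise ValueError(f"no intact copies for family {family!r}")
    length = intact.consensus_lengths[family]
    raw = np.zeros(length, dtype=np.float64)
    copies = intact.copies[family]
    for copy in copies:
        pos = track.positions.get(copy.chrom)
        if pos is None or not len(pos):
            continue
        lo, hi = np.searchsorted(pos, [copy.start, copy.end])
        inside = pos[lo:hi]
        if not len(inside):
            continue
        if copy.strand == "+":
            proj = inside - copy.start
        else:
            proj = (copy.end - 1) - inside
        np.add.at(raw, proj, 1.0)
    return MetaProfile(family, track.stage, raw, n_copies=len(copies),
                       library_size=track.library_size)


def smooth_profile(vector: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation; window must be odd.

    ``window=1`` is the identity. At the edges the window is truncated to
    the positions that exist, so the smoothed value is always a mean of
    real observations.
    """
    vector = np.asarray(vector, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(vector):
        raise ValueError("window longer than profile")
    if window == 1:
        return vector.copy()
    kernel = np.ones(window)
    sums = np.convolve(vector, kernel, mode="same")
    counts = np.convolve(np.ones_like(vector), kernel, mode="same")
    return sums / counts
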