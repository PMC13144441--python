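"""PWM library I/O and Tomtom-style footprint-to-motif matching.

Footprint sequences are converted to position frequency matrices and
compared to every library motif by an ungapped alignment over all integer
offsets. The score of an offset is the mean per-query-column Euclidean
distance between probability columns; query columns overhanging the target
are compared to the uniform background column (0.25, 0.25, 0.25, 0.25), so
spurious partial overlaps are penalized rather than silently truncated.

Statistical significance uses a permutation null: pseudo-targets are drawn
column-wise with replacement from the pooled columns of the whole library
and aligned to the query; ``p = (1 + #{null <= d*}) / (n_perm + 1)``. The
E-value is ``p`` times the number of motifs in the library, and matches with
``E < 30`` are retained (the classical loose threshold for this screen).
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import UNIFORM_COLUMN

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "Alignment",
    "read_meme",
    "write_meme",
    "sequence_to_pfm",
    "align_motifs",
    "pooled_columns",
    "null_distances",
    "match_pvalue",
    "scan_footprints",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PWM:
    """A motif as a width x 4 matrix of column-stochastic probabilities (ACGT)."""

    motif_id: str
    name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be W x 4")
        if m.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: width must be >= 4")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.name, self.matrix[::-1, ::-1])


def read_meme(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal-format motif file (ACGT alphabet)."""
    motifs: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            name = parts[2] if len(parts) > 2 else motif_id
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {motif_id}: no letter-probability matrix")
                j += 1
            if j >= len(lines):
                raise ValueError(f"motif {motif_id}: no letter-probability matrix")
            header = lines[j].strip()
            width = None
            tokens = header.replace("=", " = ").split()
            for k, tok in enumerate(tokens):
                if tok == "w" and k + 2 < len(tokens):
                    width = int(tokens[k + 2])
            if width is None:
                raise ValueError(f"motif {motif_id}: missing width in matrix header")
            rows = []
            for r in range(width):
                rows.append([float(x) for x in lines[j + 1 + r].split()])
            matrix = np.array(rows)
            if matrix.shape[1] != 4:
                raise ValueError(f"motif {motif_id}: alphabet must be ACGT (4 columns)")
            bad = np.abs(matrix.sum(axis=1) - 1.0) > 1e-3
            if bad.any():
                raise ValueError(
                    f"motif {motif_id}: non-stochastic column {int(np.argmax(bad))}"
                )
            # renormalize printed rounding, then validate strictly in PWM
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            motifs.append(PWM(motif_id, name, matrix))
            i = j + width + 1
        else:
            i += 1
    return motifs


def _format_row(row: np.ndarray) -> str:
    # print the last value as the complement so the printed row sums to
    # exactly 1.000000: parsing and renormalizing is then byte-stable
    first = [round(float(v), 6) for v in row[:3]]
    vals = first + [1.0 - sum(first)]
    return " " + " ".join(f"{v:.6f}" for v in vals)


def write_meme(motifs: Sequence[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (deterministic byte layout)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(_format_row(row) + "\n")
            fh.write("\n")


def sequence_to_pfm(sequence: str, pseudocount: float = 0.1) -> np.ndarray:
    """One-hot PFM of a DNA sequence, smoothed by a per-base pseudocount.

    Column i is ``(one_hot + pseudocount) / (1 + 4 * pseudocount)``;
    ambiguity codes give a uniform column (with a warning).
    """
    if len(sequence) < 4:
        raise ValueError("sequence must be at least 4 bp")
    w = len(sequence)
    matrix = np.zeros((w, 4))
    n_ambiguous = 0
    for i, base in enumerate(sequence.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            matrix[i] = 0.25
            n_ambiguous += 1
        else:
            matrix[i] = pseudocount
            matrix[i, idx] = 1.0 + pseudocount
            matrix[i] /= 1.0 + 4.0 * pseudocount
    if n_ambiguous:
        logger.warning("%d ambiguous bases set to uniform columns", n_ambiguous)
    return matrix


@dataclass(frozen=True)
class Alignment:
    distance: float
    offset: int
    strand: str = "+"


def _offset_range(w_query: int, w_target: int, min_overlap: int) -> range:
    return range(-(w_query - min_overlap), w_target - min_overlap + 1)


def _distance_at_offset(query: np.ndarray, target: np.ndarray, offset: int) -> float:
    wq, wt = len(query), len(target)
    i = np.arange(max(0, -offset), min(wq, wt - offset))
    aligned = np.linalg.norm(query[i] - target[i + offset], axis=1).sum()
    overhang_mask = np.ones(wq, dtype=bool)
    overhang_mask[i] = False
    overhang = np.linalg.norm(query[overhang_mask] - UNIFORM_COLUMN, axis=1).sum()
    return (aligned + overhang) / wq


def align_motifs(query: PWM | np.ndarray, target: PWM | np.ndarray,
                 min_overlap: int = 4, search_rc: bool = False) -> Alignment:
    """Best ungapped alignment of query within target over all offsets.

    Ties are broken by smaller ``|offset|``, then negative offset first,
    then '+' strand when ``search_rc`` also scores the reverse-complemented
    query.
    """
    q = query.matrix if isinstance(query, PWM) else np.asarray(query, float)
    t = target.matrix if isinstance(target, PWM) else np.asarray(target, float)
    if min_overlap < 1 or min_overlap > min(len(q), len(t)):
        raise ValueError("min_overlap must be >= 1 and <= both widths")
    candidates = [(q, "+")]
    if search_rc:
        candidates.append((q[::-1, ::-1], "-"))
    best: Alignment | None = None
    best_key = None
    for mat, strand in candidates:
        for k in _offset_range(len(mat), len(t), min_overlap):
            d = _distance_at_offset(mat, t, k)
            key = (d, abs(k), 0 if k < 0 else 1, 0 if strand == "+" else 1)
            if best_key is None or key < best_key:
                best_key = key
                best = Alignment(d, k, strand)
    assert best is not None
    return best


def pooled_columns(library: Sequence[PWM]) -> np.ndarray:
    """All probability columns of the library stacked (N x 4)."""
    if not library:
        raise ValueError("empty motif library")
    return np.concatenate([m.matrix for m in library], axis=0)


def null_distances(query: np.ndarray, target_width: int, pool: np.ndarray,
                   n_perm: int, rng: np.random.Generator,
                   min_overlap: int = 4) -> np.ndarray:
    """Best-alignment distances of the query to n_perm pooled-column pseudo-targets."""
    if not len(pool):
        raise ValueError("empty library column pool")
    idx = rng.integers(0, len(pool), size=(n_perm, target_width))
    targets = pool[idx]                                   # (n_perm, Wt, 4)
    wq = len(query)
    uniform_d = np.linalg.norm(query - UNIFORM_COLUMN, axis=1)
    total_uniform = uniform_d.sum()
    best = np.full(n_perm, np.inf)
    for k in _offset_range(wq, target_width, min_overlap):
        i = np.arange(max(0, -k), min(wq, target_width - k))
        aligned = np.linalg.norm(targets[:, i + k, :] - query[i], axis=2).sum(axis=1)
        overhang = total_uniform - uniform_d[i].sum()
        np.minimum(best, (aligned + overhang) / wq, out=best)
    return best


def match_pvalue(query: np.ndarray, target_width: int, d_star: float,
                 pool: np.ndarray, n_perm: int = 999, seed: int = 0,
                 min_overlap: int = 4) -> float:
    """Permutation p-value of an observed best distance (add-one estimator)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    null = null_distances(np.asarray(query, float), target_width, pool,
                          n_perm, rng, min_overlap)
    return float(1 + np.sum(null <= d_star)) / (n_perm + 1)


def scan_footprints(
    footprint_seqs: Mapping[str, tuple[str, str]],
    library: Sequence[PWM],
    tf_map: Mapping[str, str],
    e_threshold: float = 30.0,
    n_perm: int = 999,
    seed: int = 0,
    pseudocount: float = 0.1,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Match every footprint (both strands) against every library motif.

    ``footprint_seqs`` maps a footprint id to its (forward, reverse
    complement) consensus sequences. Returns one row per retained
    (footprint, strand, motif) pair with E < ``e_threshold``.

    Null distributions are drawn per (footprint strand, target width): the
    permutation null depends on the target only through its width, so one
    null set serves all motifs of that width, exactly.
    """
    if not library:
        raise ValueError("empty motif library")
    pool = pooled_columns(library)
    n_motifs = len(library)
    rows = []
    for fp_id in sorted(footprint_seqs):
        fwd, rev = footprint_seqs[fp_id]
        for strand, seq in (("+", fwd), ("-", rev)):
            if len(seq) < 4:
                continue
            query = sequence_to_pfm(seq, pseudocount)
            # the null stream is keyed on the query sequence itself, so the
            # same sequence gets the same null regardless of label or order
            rng = np.random.default_rng([seed, zlib.crc32(seq.encode("ascii"))])
            widths = sorted({m.width for m in library if min(len(query), m.width) >= min_overlap})
            null_by_width = {
                w: null_distances(query, w, pool, n_perm, rng, min_overlap)
                for w in widths
            }
            for motif in library:
                if min(len(query), motif.width) < min_overlap:
                    continue
                aln = align_motifs(query, motif.matrix, min_overlap=min_overlap)
                null = null_by_width[motif.width]
                p = float(1 + np.sum(null <= aln.distance)) / (n_perm + 1)
                e = p * n_motifs
                if e < e_threshold:
                    rows.append((fp_id, motif.motif_id,
                                 tf_map.get(motif.motif_id, motif.name),
                                 strand, aln.offset, aln.distance, p, e))
    return pd.DataFrame(
        rows, columns=["footprint", "motif", "tf", "strand", "offset", "distance", "p", "e"]
    )
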