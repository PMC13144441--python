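"""Repeat annotation model: consensus library, TE copies, intactness, projection.

Meta-profiles of Tn5 insertion frequency are drawn in *consensus coordinates*:
every full-length genomic copy of a TE family is projected, position by
position, onto the family's reference (Repbase-style) consensus sequence.
Projection is a linear offset and is therefore only defined for copies whose
length matches the consensus length ("intact" copies), which is exactly the
restriction applied when the profiles are built.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from ._util import encode, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusLibrary",
    "TECopy",
    "IntactSet",
    "load_annotation",
    "write_bed6",
    "select_intact",
    "place_monomers",
    "project_to_consensus",
    "consensus_to_genomic",
]


@dataclass(frozen=True)
class ConsensusLibrary:
    """Per-family consensus sequences; the coordinate frame of all profiles."""

    sequences: Mapping[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"consensus for {name!r} must be non-empty upper-case ACGTN")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ConsensusLibrary":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def __contains__(self, family: str) -> bool:
        return family in self.sequences

    @property
    def families(self) -> list[str]:
        return list(self.sequences)

    def sequence(self, family: str) -> str:
        return self.sequences[family]

    def length(self, family: str) -> int:
        return len(self.sequences[family])


@dataclass(frozen=True)
class TECopy:
    """One genomic TE insertion, 0-based half-open coordinates."""

    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    in_library: bool = True

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.copy_id}: end must be > start")
        if self.strand not in "+-":
            raise ValueError(f"{self.copy_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntactSet:
    """Copies passing the length-vs-consensus intactness rule, per family."""

    copies: dict[str, list[TECopy]]
    consensus_lengths: dict[str, int]
    tolerance_bp: int = 0

    def families(self) -> list[str]:
        return list(self.copies)

    def __getitem__(self, family: str) -> list[TECopy]:
        return self.copies[family]


def load_annotation(
    path: str | Path,
    dialect: str = "bed6",
    library: ConsensusLibrary | None = None,
) -> list[TECopy]:
    """Read a TE annotation into TECopy records with normalized coordinates.

    ``bed6`` is 0-based half-open with the family in the name column;
    ``repeatmasker_out`` is 1-based inclusive and is shifted to half-open.
    Records whose family is absent from *library* are retained but flagged
    (``in_library=False``).
    """
    if dialect not in ("bed6", "repeatmasker_out"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    copies: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "bed6":
                    fields = line.split("\t") if "\t" in line else line.split()
                    chrom, start, end, family = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    fields = line.split()
                    # RepeatMasker .out header lines start with "SW"/"score" or are blank
                    if fields[0] in ("SW", "score"):
                        continue
                    chrom = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
                    end = int(fields[6])
                    strand = "-" if fields[8] == "C" else "+"
                    family = fields[9]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if strand == ".":
                logger.warning("%s line %d: strand '.' treated as '+'", path, lineno)
                strand = "+"
            in_lib = library is None or family in library
            copies.append(
                TECopy(f"{family}.{lineno}", chrom, start, end, strand, family, in_library=in_lib)
            )
    return copies


def write_bed6(copies: Iterable[TECopy], path: str | Path) -> None:
    """Write copies as BED6 with the family name in the name column."""
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.family}\t0\t{c.strand}\n")


def select_intact(
    copies: Iterable[TECopy],
    library: ConsensusLibrary,
    tolerance_bp: int = 0,
) -> IntactSet:
    """Keep copies whose length is within ``tolerance_bp`` of the consensus length."""
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    kept: dict[str, list[TECopy]] = {}
    counts: dict[str, list[int]] = {}
    for copy in copies:
        if copy.family not in library:
            logger.warning("copy %s: family %r not in consensus library, skipped",
                           copy.copy_id, copy.family)
            continue
        counts.setdefault(copy.family, [0, 0])
        if abs(copy.length - library.length(copy.family)) <= tolerance_bp:
            kept.setdefault(copy.family, []).append(copy)
            counts[copy.family][0] += 1
        else:
            counts[copy.family][1] += 1
    for family, (n_keep, n_drop) in counts.items():
        logger.info("family %s: %d intact, %d discarded (tolerance %d bp)",
                    family, n_keep, n_drop, tolerance_bp)
    lengths = {fam: library.length(fam) for fam in kept}
    return IntactSet(copies=kept, consensus_lengths=lengths, tolerance_bp=tolerance_bp)


def place_monomers(
    genome: str,
    monomer: str,
    max_mismatches: int = 2,
    family: str = "monomer",
    chrom: str = "chr1",
) -> list[TECopy]:
    """Find all windows within Hamming distance ``max_mismatches`` of a monomer.

    Both strands are scanned; overlapping hits on the same strand are resolved
    by keeping the lower-distance hit, ties by leftmost. Used for L1-style
    5'UTR monomers, where individual tandem monomers (not whole elements) are
    the regulatory unit projected onto the consensus.
    """
    if len(monomer) < 15:
        raise ValueError("monomer length must be >= 15 bp")
    g = encode(genome)
    w = len(monomer)
    if len(g) < w:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(g, w)
    hits: list[tuple[int, int, str]] = []  # (distance, start, strand)
    for strand, probe in (("+", monomer), ("-", revcomp(monomer))):
        dist = (windows != encode(probe)).sum(axis=1)
        for pos in np.nonzero(dist <= max_mismatches)[0]:
            hits.append((int(dist[pos]), int(pos), strand))
    # greedy accept by (distance, leftmost) within each strand
    accepted: list[tuple[int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for dist, start, strand in sorted(hits, key=lambda h: (h[0], h[1])):
        span = (start, start + w)
        if any(span[0] < e and s < span[1] for s, e in occupied[strand]):
            continue
        occupied[strand].append(span)
        accepted.append((dist, start, strand))
    accepted.sort(key=lambda h: h[1])
    return [
        TECopy(f"{family}.{i + 1}", chrom, start, start + w, strand, family)
        for i, (_, start, strand) in enumerate(accepted)
    ]


def _check_projectable(copy: TECopy, consensus_length: int | None) -> None:
    if consensus_length is not None and copy.length != consensus_length:
        raise ValueError(
            f"copy {copy.copy_id} is not intact (length {copy.length} != "
            f"consensus {consensus_length}); projection undefined"
        )


def project_to_consensus(
    copy: TECopy, genomic_position: int, consensus_length: int | None = None
) -> int:
    """Map a genomic position inside an intact copy to a consensus position.

    Plus strand: ``pos - start``; minus strand: ``(end - 1) - pos``.
    """
    _check_projectable(copy, consensus_length)
    if not (copy.start <= genomic_position < copy.end):
        raise ValueError(
            f"position {genomic_position} outside copy {copy.copy_id} "
            f"[{copy.start},{copy.end})"
        )
    if copy.strand == "+":
        return genomic_position - copy.start
    return (copy.end - 1) - genomic_position


def consensus_to_genomic(
    copy: TECopy, consensus_position: int, consensus_length: int | None = None
) -> int:
    """Inverse of :func:`project_to_consensus`."""
    _check_projectable(copy, consensus_length)
    if not (0 <= consensus_position < copy.length):
        raise ValueError(f"consensus position {consensus_position} outside [0,{copy.length})")
    if copy.strand == "+":
        return copy.start + consensus_position
    return (copy.end - 1) - consensus_position
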