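"""Candidate-TF aggregation: expression filtering, merging, family profiles.

Motif-matched TFs are only credible regulators if their transcripts are
actually present when the footprint is occupied; the filter keeps a TF iff
it has at least ``min_reads`` raw reads in *every* cell of the mid- and
late-2-cell stages. Reported expression values use per-million (rpm)
library-size normalization; the filter itself deliberately uses raw counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CandidateSet",
    "rpm_normalize",
    "expression_filter",
    "merge_candidates",
    "venn_counts",
    "family_expression_profile",
]

DEFAULT_STAGES = ("zygote", "early2C", "mid2C", "late2C", "4C", "8C", "16C")
FILTER_STAGES = ("mid2C", "late2C")


@dataclass
class ExpressionMatrix:
    """Genes x cells count table with a stage label per cell column."""

    counts: pd.DataFrame              # index = genes, columns = cell ids
    stages: pd.Series                 # index = cell ids, values = stage labels

    def __post_init__(self):
        self.stages = pd.Series(self.stages)
        if list(self.stages.index) != list(self.counts.columns):
            raise ValueError("stage labels must cover exactly the cell columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def columns_for(self, stages: Iterable[str]) -> list[str]:
        stages = set(stages)
        return [c for c in self.counts.columns if self.stages[c] in stages]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\t" + "\t".join(self.stages[c] for c in self.counts.columns) + "\n")
            fh.write("gene\t" + "\t".join(self.counts.columns) + "\n")
            for gene, row in self.counts.iterrows():
                fh.write(gene + "\t" + "\t".join(str(v) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            stage_row = fh.readline().rstrip("\n").split("\t")
            header = fh.readline().rstrip("\n").split("\t")
            if stage_row[0] != "stage" or header[0] != "gene":
                raise ValueError(f"{path}: expected 'stage' then 'gene' header rows")
            cells = header[1:]
            stages = pd.Series(stage_row[1:], index=cells)
            data, genes = [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                genes.append(f[0])
                data.append([float(x) for x in f[1:]])
        counts = pd.DataFrame(data, index=genes, columns=cells)
        return cls(counts, stages)


def rpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each column by its library size, times 1e6 (reads per million)."""
    sizes = matrix.library_sizes
    zero = sizes[sizes <= 0]
    if len(zero):
        raise ValueError(f"zero-sum column(s): {list(zero.index)}")
    rpm = matrix.counts / sizes * 1e6
    return ExpressionMatrix(rpm, matrix.stages.copy())


def expression_filter(
    matrix: ExpressionMatrix,
    tf_list: Sequence[str],
    stages: Iterable[str] = FILTER_STAGES,
    min_reads: int = 2,
) -> list[str]:
    """Keep TFs with >= min_reads raw reads in every cell of the given stages."""
    stages = list(stages)
    for stage in stages:
        if not any(matrix.stages == stage):
            raise ValueError(f"no cells labelled with stage {stage!r}")
    cols = matrix.columns_for(stages)
    retained = []
    for tf in tf_list:
        if tf not in matrix.counts.index:
            logger.warning("TF %s absent from expression matrix, dropped", tf)
            continue
        if (matrix.counts.loc[tf, cols] >= min_reads).all():
            retained.append(tf)
    return retained


@dataclass
class CandidateSet:
    """Per-family candidate TF lists plus their merged union."""

    per_family: dict[str, list[str]]
    merged: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def merge_candidates(matches_by_family: Mapping[str, pd.DataFrame]) -> CandidateSet:
    """Group matches per family into unique TF lists and their union.

    A TF matched by several motifs, footprints, or strands appears once per
    family; provenance keeps the number of supporting matches and the best
    E-value per TF x family.
    """
    per_family: dict[str, list[str]] = {}
    prov_rows = []
    for family in sorted(matches_by_family):
        df = matches_by_family[family]
        if df is None or not len(df):
            per_family[family] = []
            continue
        per_family[family] = sorted(df["tf"].unique())
        for tf, grp in df.groupby("tf"):
            prov_rows.append({
                "family": family,
                "tf": tf,
                "n_matches": len(grp),
                "best_e": float(grp["e"].min()) if "e" in grp else np.nan,
                "footprints": ",".join(sorted(map(str, grp["footprint"].unique())))
                if "footprint" in grp else "",
                "strands": ",".join(sorted(grp["strand"].unique()))
                if "strand" in grp else "",
            })
    merged = sorted(set().union(*per_family.values())) if per_family else []
    prov = pd.DataFrame(prov_rows)
    return CandidateSet(per_family=per_family, merged=merged, provenance=prov)


def venn_counts(candidate_set: CandidateSet) -> pd.DataFrame:
    """Exclusive intersection-region sizes of the per-family candidate sets.

    One row per non-empty subset of families; ``count`` is the number of TFs
    in exactly that combination of families, so counts sum to the union size.
    """
    families = sorted(candidate_set.per_family)
    if len(families) < 2:
        raise ValueError("venn_counts needs at least 2 families")
    sets = {f: set(candidate_set.per_family[f]) for f in families}
    membership: dict[frozenset, int] = {}
    for tf in set().union(*sets.values()):
        key = frozenset(f for f in families if tf in sets[f])
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(families) + 1):
        for combo in combinations(families, r):
            key = frozenset(combo)
            rows.append({"region": "&".join(combo), "count": membership.get(key, 0)})
    return pd.DataFrame(rows)


def family_expression_profile(
    insertions: pd.DataFrame,
    family: str,
    ercc_factors: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-embryo summed rpm over all insertions of a family, plus stage means.

    ``insertions`` has one row per (embryo, insertion) with columns
    ``embryo``, ``stage``, ``family``, ``rpm``. If ERCC spike-in factors are
    given, each embryo's sum is divided by its factor (absolute-scale
    normalization). The stage means are the trend line across development.
    """
    sub = insertions[insertions["family"] == family]
    if not len(sub):
        raise ValueError(f"unknown family {family!r} (no insertions)")
    per_embryo = (
        sub.groupby(["embryo", "stage"], sort=False)["rpm"].sum().reset_index(name="sum_rpm")
    )
    if ercc_factors is not None:
        per_embryo["sum_rpm"] = [
            v / ercc_factors[e] for e, v in zip(per_embryo["embryo"], per_embryo["sum_rpm"])
        ]
    stage_means = per_embryo.groupby("stage", sort=False)["sum_rpm"].mean()
    return per_embryo, stage_means
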