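"""Synthetic TE genome, ATAC insertion, motif-library and expression simulator.

Generates a fully specified toy dataset so every downstream stage of the
footprinting pipeline can be exercised with no external download:

* a random genome with planted TE copies per family (full-length "intact"
  copies and 3'-truncated ones), each copy carrying i.i.d. substitutions
  except at planted TF binding sites, which are never mutated;
* per-stage Tn5 insertion events drawn Poisson per position, with elements
  more accessible than background by ``background_rate_ratio`` and planted
  sites protected by the multiplicative factor ``protection_factor`` (rho)
  at the stages where the site is occupied — rho is the in-site/flank
  insertion-rate ratio, so rho = 0 is full protection and rho = 1 none;
* a MEME-format motif library containing the planted site motifs plus
  random Dirichlet-column decoys;
* a single-cell count matrix in which planted TFs always have >= 2 reads in
  every mid/late-2-cell cell while decoys are lowly expressed, so the
  downstream expression filter separates them.

Everything is deterministic given ``SimulationConfig.seed``: each stage of
the generator draws from its own seeded stream, and identical configs give
byte-identical output files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import decode, encode
from .candidates import DEFAULT_STAGES, FILTER_STAGES, ExpressionMatrix
from .motifs import PWM, write_meme
from .profiles import InsertionTrack, write_fragments_bedpe
from .repeats import ConsensusLibrary, TECopy, write_bed6

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSite",
    "FamilySpec",
    "SimulationConfig",
    "TruthBundle",
    "SimulatedDataset",
    "default_config",
    "make_te_genome",
    "simulate_atac",
    "cuts_to_fragments",
    "make_motif_library",
    "site_pwm",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedSite:
    """A TF binding site planted at a consensus interval of a family."""

    start: int
    end: int
    motif_id: str
    occupied_stages: tuple[str, ...]


@dataclass(frozen=True)
class FamilySpec:
    name: str
    consensus: str
    n_intact_copies: int
    n_truncated_copies: int = 0
    planted_sites: tuple[PlantedSite, ...] = ()

    def validate(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"family {self.name}: consensus must be non-empty upper-case ACGT")
        length = len(self.consensus)
        spans = sorted((s.start, s.end) for s in self.planted_sites)
        for s in self.planted_sites:
            if not (0 <= s.start < s.end <= length):
                raise ValueError(f"family {self.name}: planted site outside consensus")
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"family {self.name}: overlapping planted sites")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    genome_length: int = 120_000
    families: tuple[FamilySpec, ...] = ()
    stages: tuple[str, ...] = ("early2C", "late2C", "8C")
    depth_per_stage: float = 15_000.0
    protection_factor: float = 0.15       # rho: in-site insertion-rate factor when occupied
    background_rate_ratio: float = 20.0   # element vs background insertion-rate ratio
    copy_mutation_rate: float = 0.02
    n_cells_per_stage: int = 10
    tf_count_high: float = 10.0           # expected per-cell counts, planted TFs
    tf_count_low: float = 1.0             # expected per-cell counts, decoy TFs
    n_decoy_motifs: int = 25
    expression_stages: tuple[str, ...] = DEFAULT_STAGES

    def validate(self) -> None:
        if not (0.0 <= self.protection_factor <= 1.0):
            raise ValueError("protection_factor must be in [0, 1]")
        if not self.families:
            raise ValueError("config needs at least one family")
        total = sum(
            len(f.consensus) * (f.n_intact_copies + f.n_truncated_copies)
            for f in self.families
        )
        if self.genome_length < total:
            raise ValueError("genome_length smaller than the sum of planted copy lengths")
        if self.tf_count_high < 2:
            raise ValueError("tf_count_high must be >= 2")
        if self.n_cells_per_stage < 2:
            raise ValueError("n_cells_per_stage must be >= 2")
        for fam in self.families:
            fam.validate()
            for site in fam.planted_sites:
                for stage in site.occupied_stages:
                    if stage not in self.stages:
                        raise ValueError(f"unknown occupied stage {stage!r}")


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the synthetic data."""

    copies: pd.DataFrame          # copy_id, chrom, start, end, strand, family, intact
    sites: pd.DataFrame           # family, start, end, motif_id, occupied_stages
    planted_tfs: list[str]
    decoy_tfs: list[str] = field(default_factory=list)
    planted_pwms: dict[str, PWM] = field(default_factory=dict)
    tf_map: dict[str, str] = field(default_factory=dict)


CHROM = "chrSim"


def _tf_name_for(motif_id: str) -> str:
    return motif_id.removeprefix("M_")


def default_config(seed: int = 42) -> SimulationConfig:
    """The standard two-family study conditions used throughout the tests.

    Two 300-bp LTR-like families with 50 intact + 10 truncated copies each;
    five planted 14-15 bp sites (three in family simLTR1, two in simLTR2)
    occupied mostly at the late 2-cell stage; aggregated in-element depth
    of ~0.4 insertions per bp per copy (~20/bp over 50 copies); rho = 0.15.
    """
    rng = np.random.default_rng([seed, 101])
    cons = [decode(rng.integers(0, 4, 300).astype(np.uint8)) for _ in range(2)]
    fam1 = FamilySpec(
        name="simLTR1",
        consensus=cons[0],
        n_intact_copies=50,
        n_truncated_copies=10,
        planted_sites=(
            PlantedSite(80, 95, "M_TF1", ("late2C",)),
            PlantedSite(150, 164, "M_TF2", ("early2C", "late2C")),
            PlantedSite(220, 235, "M_TF3", ("late2C",)),
        ),
    )
    fam2 = FamilySpec(
        name="simLTR2",
        consensus=cons[1],
        n_intact_copies=50,
        n_truncated_copies=10,
        planted_sites=(
            PlantedSite(100, 115, "M_TF4", ("late2C",)),
            PlantedSite(200, 214, "M_TF5", ("late2C",)),
        ),
    )
    return SimulationConfig(seed=seed, families=(fam1, fam2))


class GenomeTooSmallError(RuntimeError):
    pass


def site_pwm(sequence: str, motif_id: str, tf_name: str, peak: float = 0.85) -> PWM:
    """A peaked PWM matching a planted site sequence (peak on the site base)."""
    other = (1.0 - peak) / 3.0
    matrix = np.full((len(sequence), 4), other)
    matrix[np.arange(len(sequence)), encode(sequence)] = peak
    return PWM(motif_id, tf_name, matrix)


def make_te_genome(config: SimulationConfig
                   ) -> tuple[str, list[TECopy], TruthBundle]:
    """Plant TE copies in a random genome and report the ground truth.

    Intact copies have exactly the consensus length; truncated ones lose a
    random portion of the 3' end. Substitutions hit each copy base i.i.d. at
    ``copy_mutation_rate`` except inside planted sites. Copies never overlap
    (10 bp guard gap); placement failure after bounded retries raises
    :class:`GenomeTooSmallError`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genome = rng.integers(0, 4, config.genome_length).astype(np.uint8)
    placed: list[tuple[int, int]] = []
    pad = 10

    def try_place(length: int) -> int:
        for _ in range(1000):
            s = int(rng.integers(0, config.genome_length - length + 1))
            e = s + length
            if all(e + pad <= ps or pe + pad <= s for ps, pe in placed):
                placed.append((s, e))
                return s
        raise GenomeTooSmallError("genome too small: copy placement failed after 1000 retries")

    copies: list[TECopy] = []
    truth_rows = []
    site_rows = []
    planted_pwms: dict[str, PWM] = {}
    for fam in config.families:
        cons = encode(fam.consensus)
        length_full = len(cons)
        protected = np.zeros(length_full, dtype=bool)
        for site in fam.planted_sites:
            protected[site.start:site.end] = True
            seq = fam.consensus[site.start:site.end]
            planted_pwms[site.motif_id] = site_pwm(
                seq, site.motif_id, _tf_name_for(site.motif_id))
            site_rows.append({
                "family": fam.name, "start": site.start, "end": site.end,
                "motif_id": site.motif_id,
                "occupied_stages": ",".join(site.occupied_stages),
            })
        lengths = [length_full] * fam.n_intact_copies
        for _ in range(fam.n_truncated_copies):
            lengths.append(int(rng.integers(max(20, length_full // 3),
                                            max(21, (4 * length_full) // 5))))
        for i, length in enumerate(lengths):
            start = try_place(length)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = cons[:length].copy()
            if config.copy_mutation_rate > 0:
                hit = rng.random(length) < config.copy_mutation_rate
                hit &= ~protected[:length]
                n_hit = int(hit.sum())
                if n_hit:
                    seq[hit] = (seq[hit] + rng.integers(1, 4, n_hit).astype(np.uint8)) % 4
            if strand == "-":
                seq = (3 - seq)[::-1]
            genome[start:start + length] = seq
            copy_id = f"{fam.name}.{i + 1}"
            copies.append(TECopy(copy_id, CHROM, start, start + length, strand, fam.name))
            truth_rows.append({
                "copy_id": copy_id, "chrom": CHROM, "start": start,
                "end": start + length, "strand": strand, "family": fam.name,
                "intact": length == length_full,
            })
    copies.sort(key=lambda c: c.start)
    truth = TruthBundle(
        copies=pd.DataFrame(truth_rows).sort_values("start").reset_index(drop=True),
        sites=pd.DataFrame(site_rows),
        planted_tfs=sorted(_tf_name_for(m) for m in planted_pwms),
        planted_pwms=planted_pwms,
        tf_map={m: _tf_name_for(m) for m in planted_pwms},
    )
    return decode(genome), copies, truth


def _site_genomic_span(copy: TECopy, full_length: int, c_start: int, c_end: int
                       ) -> tuple[int, int] | None:
    """Genomic span of a consensus interval within a (possibly truncated) copy.

    Truncation removes the 3' end, so only consensus positions < copy length
    survive. Returns None if the whole site is lost.
    """
    c_end = min(c_end, copy.length)
    if c_start >= c_end:
        return None
    if copy.strand == "+":
        return copy.start + c_start, copy.start + c_end
    return copy.end - c_end, copy.end - c_start


def simulate_atac(
    config: SimulationConfig,
    copies: Sequence[TECopy],
    truth: TruthBundle,
) -> tuple[dict[str, InsertionTrack], dict[str, pd.DataFrame]]:
    """Per-stage single-base Tn5 insertion events.

    Relative rate is 1 in background, ``background_rate_ratio`` inside TE
    copies, times ``protection_factor`` inside occupied planted sites; the
    rate vector is scaled so the expected stage total is
    ``depth_per_stage``, and counts are Poisson per position. If a stage's
    total is odd, one uniformly chosen event is dropped so the event list
    pairs cleanly into fragments.

    Returns (tracks, event tables); each event table has chrom/pos/strand.
    """
    base = np.ones(config.genome_length)
    for copy in copies:
        base[copy.start:copy.end] = config.background_rate_ratio
    by_family: dict[str, list[TECopy]] = {}
    for copy in copies:
        by_family.setdefault(copy.family, []).append(copy)
    spans_by_stage: dict[str, list[tuple[int, int]]] = {s: [] for s in config.stages}
    for site in truth.sites.itertuples(index=False):
        occupied = site.occupied_stages.split(",")
        full_length = len(next(f.consensus for f in config.families
                               if f.name == site.family))
        for copy in by_family.get(site.family, []):
            span = _site_genomic_span(copy, full_length, site.start, site.end)
            if span is None:
                continue
            for stage in occupied:
                spans_by_stage[stage].append(span)
    tracks: dict[str, InsertionTrack] = {}
    events: dict[str, pd.DataFrame] = {}
    for si, stage in enumerate(config.stages):
        rng = np.random.default_rng([config.seed, 2, si])
        w = base.copy()
        for a, b in spans_by_stage[stage]:
            w[a:b] *= config.protection_factor
        w *= config.depth_per_stage / w.sum()
        counts = rng.poisson(w)
        pos = np.repeat(np.arange(config.genome_length), counts)
        if len(pos) % 2:
            pos = np.delete(pos, int(rng.integers(len(pos))))
        strands = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        events[stage] = pd.DataFrame({"chrom": CHROM, "pos": pos, "strand": strands})
        tracks[stage] = InsertionTrack(stage, {CHROM: pos.copy()}, library_size=len(pos))
    return tracks, events


def cuts_to_fragments(track: InsertionTrack) -> pd.DataFrame:
    """Pair consecutive cut events into fragments (chrom, start, end).

    A fragment's two cuts are its start and ``end - 1``, so converting back
    with zero shifts reproduces the track exactly. Requires an even event
    count per chromosome (the simulator guarantees this).
    """
    rows = []
    for chrom in sorted(track.positions):
        pos = track.positions[chrom]
        if len(pos) % 2:
            raise ValueError(f"{chrom}: odd number of cut events cannot pair into fragments")
        for a, b in zip(pos[0::2], pos[1::2]):
            rows.append((chrom, int(a), int(b) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_motif_library(
    planted: Sequence[PWM],
    n_decoys: int,
    seed: int | Sequence[int],
    decoy_widths: tuple[int, int] = (6, 12),
    dirichlet_alpha: float = 0.5,
) -> tuple[list[PWM], list[str], list[str]]:
    """Planted motifs plus random Dirichlet-column decoys.

    Returns (library, planted ids, decoy ids); decoy TF names are derivable
    from their motif ids. Duplicate motif ids raise.
    """
    rng = np.random.default_rng(seed)
    library = list(planted)
    ids = [m.motif_id for m in library]
    decoy_ids = []
    for i in range(n_decoys):
        w = int(rng.integers(decoy_widths[0], decoy_widths[1] + 1))
        matrix = rng.dirichlet(np.full(4, dirichlet_alpha), size=w)
        motif_id = f"M_DTF{i + 1:02d}"
        library.append(PWM(motif_id, _tf_name_for(motif_id), matrix))
        ids.append(motif_id)
        decoy_ids.append(motif_id)
    if len(set(ids)) != len(ids):
        dup = sorted({m for m in ids if ids.count(m) > 1})
        raise ValueError(f"duplicate motif id(s): {dup}")
    return library, [m.motif_id for m in planted], decoy_ids


def simulate_expression(
    planted_tfs: Sequence[str],
    decoy_tfs: Sequence[str],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Count matrix in which planted TFs pass the >= 2-reads filter and decoys don't.

    Planted TFs draw Poisson(``tf_count_high``) in mid/late-2-cell cells,
    rejection-resampled until every such cell has >= 2 reads; decoys and all
    other stages draw Poisson(``tf_count_low``).
    """
    if config.tf_count_high < 2:
        raise ValueError("tf_count_high must be >= 2")
    rng = np.random.default_rng([config.seed, 3])
    genes = list(planted_tfs) + list(decoy_tfs)
    cells, stages = [], []
    for stage in config.expression_stages:
        for j in range(config.n_cells_per_stage):
            cells.append(f"{stage}_c{j + 1}")
            stages.append(stage)
    counts = rng.poisson(config.tf_count_low, size=(len(genes), len(cells)))
    filter_cols = [i for i, s in enumerate(stages) if s in FILTER_STAGES]
    n_planted = len(planted_tfs)
    block = rng.poisson(config.tf_count_high, size=(n_planted, len(filter_cols)))
    while (block < 2).any():
        low = block < 2
        block[low] = rng.poisson(config.tf_count_high, size=int(low.sum()))
    counts[np.ix_(range(n_planted), filter_cols)] = block
    df = pd.DataFrame(counts, index=genes, columns=cells)
    return ExpressionMatrix(df, pd.Series(stages, index=cells))


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    genome: str
    copies: list[TECopy]
    truth: TruthBundle
    tracks: dict[str, InsertionTrack]
    events: dict[str, pd.DataFrame]
    fragments: dict[str, pd.DataFrame]
    motif_library: list[PWM]
    expression: ExpressionMatrix

    @property
    def consensus_library(self) -> ConsensusLibrary:
        return ConsensusLibrary({f.name: f.consensus for f in self.config.families})


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the full generator: genome, ATAC, fragments, motifs, expression."""
    config = config or default_config()
    genome, copies, truth = make_te_genome(config)
    tracks, events = simulate_atac(config, copies, truth)
    fragments = {stage: cuts_to_fragments(tracks[stage]) for stage in config.stages}
    planted = [truth.planted_pwms[m] for m in sorted(truth.planted_pwms)]
    library, _, decoy_ids = make_motif_library(
        planted, config.n_decoy_motifs, [config.seed, 4])
    truth.decoy_tfs = [_tf_name_for(m) for m in decoy_ids]
    truth.tf_map.update({m: _tf_name_for(m) for m in decoy_ids})
    expression = simulate_expression(truth.planted_tfs, truth.decoy_tfs, config)
    return SimulatedDataset(config, genome, copies, truth, tracks, events,
                            fragments, library, expression)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the dataset files (FASTA/BED/BEDPE/MEME/TSV, byte-deterministic)."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(ds.genome), 70):
            fh.write(ds.genome[i:i + 70] + "\n")
    with open(outdir / "consensus.fa", "w") as fh:
        for fam in ds.config.families:
            fh.write(f">{fam.name}\n{fam.consensus}\n")
    write_bed6(ds.copies, outdir / "te_annotation.bed")
    for stage, ev in ds.events.items():
        with open(outdir / f"insertions.{stage}.bed", "w") as fh:
            for chrom, pos, strand in ev.itertuples(index=False):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")
        write_fragments_bedpe(ds.fragments[stage], outdir / f"fragments.{stage}.bedpe")
    write_meme(ds.motif_library, outdir / "motifs.meme")
    with open(outdir / "tf_map.tsv", "w") as fh:
        fh.write("motif_id\ttf\n")
        for motif_id in sorted(ds.truth.tf_map):
            fh.write(f"{motif_id}\t{ds.truth.tf_map[motif_id]}\n")
    ds.expression.to_tsv(outdir / "expression.tsv")
    ds.truth.copies.to_csv(outdir / "truth" / "copies.tsv", sep="\t", index=False)
    ds.truth.sites.to_csv(outdir / "truth" / "sites.tsv", sep="\t", index=False)
    with open(outdir / "truth" / "tfs.tsv", "w") as fh:
        fh.write("tf\trole\n")
        for tf in ds.truth.planted_tfs:
            fh.write(f"{tf}\tplanted\n")
        for tf in ds.truth.decoy_tfs:
            fh.write(f"{tf}\tdecoy\n")
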