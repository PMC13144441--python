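"""Generator contracts: planted copies, protection, determinism, expression truth."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tefoot import expression_filter, simulate_dataset, write_dataset
from tefoot.motifs import read_meme
from tefoot.simulate import (
    FamilySpec,
    PlantedSite,
    SimulationConfig,
    default_config,
    make_motif_library,
    make_te_genome,
    simulate_atac,
    simulate_expression,
    site_pwm,
)
from tefoot._util import revcomp


def _one_family_config(seed=1, mutation=0.0, n_intact=5, sites=(), length=300,
                       genome_length=30_000, **kw):
    rng = np.random.default_rng(123)
    consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    fam = FamilySpec("famX", consensus, n_intact, 0, sites)
    return SimulationConfig(seed=seed, genome_length=genome_length,
                            families=(fam,), copy_mutation_rate=mutation, **kw)


def _extract(genome, row):
    seq = genome[row.start:row.end]
    return revcomp(seq) if row.strand == "-" else seq


class TestMakeTeGenome:
    def test_mutation_free_copies_equal_consensus(self):
        config = _one_family_config(mutation=0.0)
        genome, copies, truth = make_te_genome(config)
        assert len(copies) == 5
        consensus = config.families[0].consensus
        for row in truth.copies.itertuples(index=False):
            assert row.end - row.start == 300
            assert _extract(genome, row) == consensus

    def test_identical_seed_identical_output(self):
        config = _one_family_config(mutation=0.02)
        g1, c1, t1 = make_te_genome(config)
        g2, c2, t2 = make_te_genome(config)
        assert g1 == g2
        assert c1 == c2
        pd.testing.assert_frame_equal(t1.copies, t2.copies)

    def test_mismatch_fraction_matches_mutation_rate(self):
        # oracle: direct pairwise comparison of extracted copies vs consensus
        config = _one_family_config(seed=7, mutation=0.02, n_intact=50,
                                    genome_length=40_000)
        genome, copies, truth = make_te_genome(config)
        consensus = config.families[0].consensus
        fractions = []
        for row in truth.copies.itertuples(index=False):
            seq = _extract(genome, row)
            mism = sum(a != b for a, b in zip(seq, consensus))
            fractions.append(mism / 300)
        assert abs(np.mean(fractions) - 0.02) < 0.01

    def test_planted_sites_never_mutated(self):
        site = PlantedSite(120, 135, "M_TFA", ("late2C",))
        config = _one_family_config(seed=3, mutation=0.2, n_intact=20,
                                    sites=(site,), genome_length=40_000)
        genome, copies, truth = make_te_genome(config)
        consensus = config.families[0].consensus
        for row in truth.copies.itertuples(index=False):
            assert _extract(genome, row)[120:135] == consensus[120:135]

    def test_genome_too_small_raises(self):
        config = _one_family_config(genome_length=30_000)
        config = dataclasses.replace(config, genome_length=1_501)
        with pytest.raises(Exception, match="too small|smaller"):
            make_te_genome(config)

    def test_overlapping_planted_sites_rejected(self):
        sites = (PlantedSite(100, 120, "M_A", ("late2C",)),
                 PlantedSite(110, 130, "M_B", ("late2C",)))
        with pytest.raises(ValueError, match="overlap"):
            make_te_genome(_one_family_config(sites=sites))


class TestSimulateAtac:
    @staticmethod
    def _site_rates(config):
        genome, copies, truth = make_te_genome(config)
        tracks, _ = simulate_atac(config, copies, truth)
        fam = config.families[0]
        site = fam.planted_sites[0]
        in_site = np.zeros(len(fam.consensus))
        for copy in copies:
            pos = tracks["late2C"].positions[copy.chrom]
            inside = pos[(pos >= copy.start) & (pos < copy.end)]
            proj = inside - copy.start if copy.strand == "+" else (copy.end - 1) - inside
            np.add.at(in_site, proj, 1)
        centre = in_site[site.start:site.end]
        flank = np.concatenate([in_site[site.start - 25:site.start],
                                in_site[site.end:site.end + 25]])
        return centre, flank

    def test_rho_zero_gives_zero_in_site_insertions(self):
        site = PlantedSite(120, 135, "M_TFA", ("late2C",))
        config = _one_family_config(seed=5, n_intact=30, sites=(site,),
                                    genome_length=40_000, protection_factor=0.0,
                                    depth_per_stage=30_000.0)
        centre, _ = self._site_rates(config)
        assert centre.sum() == 0

    def test_rho_one_means_no_footprint(self):
        site = PlantedSite(120, 135, "M_TFA", ("late2C",))
        config = _one_family_config(seed=5, n_intact=50, sites=(site,),
                                    genome_length=60_000, protection_factor=1.0,
                                    depth_per_stage=100_000.0)
        centre, flank = self._site_rates(config)
        diff = centre.mean() - flank.mean()
        se = np.sqrt(flank.mean() / len(centre) + flank.mean() / len(flank))
        assert abs(diff) < 3 * se

    def test_rho_quarter_depletion_ratio(self):
        # oracle: the generative model sets in-site rate = rho * element rate
        site = PlantedSite(120, 135, "M_TFA", ("late2C",))
        config = _one_family_config(seed=5, n_intact=50, sites=(site,),
                                    genome_length=60_000, protection_factor=0.2,
                                    depth_per_stage=40_000.0)
        centre, flank = self._site_rates(config)
        assert 0.1 <= centre.mean() / flank.mean() <= 0.3

    def test_total_insertions_near_configured_depth(self):
        config = _one_family_config(depth_per_stage=5_000.0)
        genome, copies, truth = make_te_genome(config)
        tracks, _ = simulate_atac(config, copies, truth)
        for track in tracks.values():
            assert abs(track.n_events - 5_000) < 4 * np.sqrt(5_000) + 1

    def test_even_event_count_per_stage(self):
        config = _one_family_config()
        genome, copies, truth = make_te_genome(config)
        tracks, _ = simulate_atac(config, copies, truth)
        for track in tracks.values():
            assert track.n_events % 2 == 0


class TestMotifLibrary:
    def test_roundtrip_and_column_sums(self, tmp_path):
        planted = [site_pwm("ACGTACGTAC", "M_A", "A"), site_pwm("GGGTTTCCCA", "M_B", "B")]
        library, planted_ids, decoy_ids = make_motif_library(planted, 3, seed=1)
        from tefoot.motifs import write_meme
        path = tmp_path / "m.meme"
        write_meme(library, path)
        parsed = read_meme(path)
        assert len(parsed) == 5
        for m in parsed:
            np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_byte_identical_given_seed(self, tmp_path):
        from tefoot.motifs import write_meme
        planted = [site_pwm("ACGTACGTAC", "M_A", "A")]
        paths = []
        for i in range(2):
            lib, _, _ = make_motif_library(planted, 4, seed=9)
            p = tmp_path / f"m{i}.meme"
            write_meme(lib, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_decoys_distinct_from_planted(self):
        # oracle: exhaustive pairwise column-distance scan
        planted = [site_pwm("ACGTACGTAC", "M_A", "A"), site_pwm("GGGTTTCCCA", "M_B", "B")]
        library, planted_ids, decoy_ids = make_motif_library(planted, 5, seed=0)
        planted_cols = np.concatenate([m.matrix for m in library
                                       if m.motif_id in planted_ids])
        for decoy in library:
            if decoy.motif_id not in decoy_ids:
                continue
            dmin = min(np.linalg.norm(col - pc)
                       for col in decoy.matrix for pc in planted_cols)
            assert dmin > 0

    def test_duplicate_motif_id_rejected(self):
        planted = [site_pwm("ACGTACGTAC", "M_DTF01", "DTF01")]
        with pytest.raises(ValueError, match="duplicate"):
            make_motif_library(planted, 2, seed=0)


class TestSimulateExpression:
    def test_planted_pass_and_shape(self):
        config = default_config(1)
        em = simulate_expression(["TF1", "TF2"], ["D1", "D2"], config)
        n_stages = len(config.expression_stages)
        assert em.counts.shape == (4, n_stages * config.n_cells_per_stage)
        cols = em.columns_for(["mid2C", "late2C"])
        assert (em.counts.loc[["TF1", "TF2"], cols] >= 2).all().all()

    def test_some_decoy_fails_filter_under_default_seed(self, default_ds):
        em = default_ds.expression
        cols = em.columns_for(["mid2C", "late2C"])
        decoys = em.counts.loc[default_ds.truth.decoy_tfs, cols]
        assert (decoys < 2).any().any()

    def test_filter_recovers_exactly_planted(self, default_ds):
        # oracle: the >=2-in-all-cells rule applied directly to the matrix
        em = default_ds.expression
        all_tfs = list(em.counts.index)
        retained = expression_filter(em, all_tfs)
        cols = em.columns_for(["mid2C", "late2C"])
        by_hand = [tf for tf in all_tfs
                   if (em.counts.loc[tf, cols] >= 2).all()]
        assert retained == by_hand == default_ds.truth.planted_tfs

    def test_low_high_count_rejected(self):
        config = dataclasses.replace(default_config(1), tf_count_high=1.5)
        with pytest.raises(ValueError, match=">= 2"):
            simulate_expression(["TF1"], ["D1"], config)


def test_write_dataset_byte_reproducible(tmp_path, tiny_config):
    dirs = []
    for i in range(2):
        ds = simulate_dataset(tiny_config)
        out = tmp_path / f"run{i}"
        out.mkdir()
        write_dataset(ds, out)
        dirs.append(out)
    files = sorted(p.relative_to(dirs[0]) for p in dirs[0].rglob("*") if p.is_file())
    assert files
    for rel in files:
        assert (dirs[0] / rel).read_bytes() == (dirs[1] / rel).read_bytes()
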