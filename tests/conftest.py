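"""Shared fixtures: one simulated dataset and pipeline run reused across tests."""
from __future__ import annotations

import numpy as np
import pytest

from tefoot import default_config, recover_tfs, simulate_dataset
from tefoot.simulate import FamilySpec, PlantedSite, SimulationConfig


@pytest.fixture(scope="session")
def default_ds():
    """The standard two-family study-conditions dataset (seed 42)."""
    return simulate_dataset(default_config(42))


@pytest.fixture(scope="session")
def pipeline_result(default_ds):
    """Full candidate-recovery run on the standard dataset."""
    return recover_tfs(default_ds, seed=0)


@pytest.fixture()
def tiny_config():
    """One small mutation-free family, handy for exact checks."""
    rng = np.random.default_rng(7)
    consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    fam = FamilySpec(
        name="fam1",
        consensus=consensus,
        n_intact_copies=5,
        n_truncated_copies=0,
        planted_sites=(PlantedSite(120, 135, "M_TFA", ("late2C",)),),
    )
    return SimulationConfig(
        seed=1,
        genome_length=20_000,
        families=(fam,),
        depth_per_stage=2_000.0,
        copy_mutation_rate=0.0,
    )
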