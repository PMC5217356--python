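import numpy as np
import pandas as pd
import pytest

from cwpquant import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A modest seeded experiment shared by read-only tests."""
    cfg = SimulationConfig(n_proteins=60, seed=11, affected_stage=2)
    obs, annot, truth = simulate_experiment(cfg)
    return cfg, obs, annot, truth


def make_observations(rows):
    """Build an observation DataFrame from (seq, z, mz, prots, stage,
    rep, slice, xic) tuples."""
    return pd.DataFrame(
        rows, columns=["peptide_sequence", "charge", "mz",
                       "protein_accessions", "stage", "replicate",
                       "slice", "xic"])


@pytest.fixture
def toy_obs():
    return make_observations
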