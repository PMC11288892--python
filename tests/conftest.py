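"""Shared fixtures: small synthetic datasets and fitted pipelines.

The expensive GP-pipeline fits are session-scoped so several test modules
can share one run.
"""

import numpy as np
import pandas as pd
import pytest

import meltshift as ms


@pytest.fixture(scope="session")
def shifted_specs():
    """Twelve proteins, all archetypes, 4 C osmolyte stabilization."""
    return ms.make_protein_specs(12, seed=101, delta_Tm=4.0, n_ht_peptides=2)


@pytest.fixture(scope="session")
def shifted_dataset(shifted_specs):
    return ms.simulate_lip_experiment(
        shifted_specs, ms.SimNoiseModel(sigma=0.05), seed=102
    )


@pytest.fixture(scope="session")
def shifted_results(shifted_dataset):
    return ms.ThermalShiftModel(shifted_dataset).fit(seed=0)


@pytest.fixture(scope="session")
def toy_table():
    """Minimal 4-row long table: 1 peptide, 2 temperatures, 2 replicates."""
    return pd.DataFrame({
        "protein_id": ["P1"] * 4,
        "peptide": ["PEPTIDEK"] * 4,
        "start": [10] * 4,
        "end": [17] * 4,
        "tryptic_type": ["FT"] * 4,
        "condition": ["control"] * 4,
        "replicate": [1, 2, 1, 2],
        "temperature_C": [37.0, 37.0, 76.0, 76.0],
        "intensity": [100.0, 110.0, 10.0, 12.0],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
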