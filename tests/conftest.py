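import warnings

import numpy as np
import pandas as pd
import pytest

from apmsnet import ScoringOptions, SynthConfig, generate_apms_dataset

# scoring at high id thresholds legitimately empties the control table
warnings.filterwarnings("ignore", message="all records removed")


@pytest.fixture(scope="session")
def small_screen():
    """A compact screen with planted interactions, shared across tests."""
    config = SynthConfig(
        n_baits=3, n_preys=30, n_controls=3, n_replicates=4, planted_density=0.1, seed=11
    )
    table, controls, truth = generate_apms_dataset(config)
    return config, table, controls, truth


@pytest.fixture()
def default_options():
    return ScoringOptions()


def make_spectral_table(rows):
    """rows: (bait, prey, replicate, count, id_score)"""
    return pd.DataFrame(rows, columns=["bait", "prey", "replicate", "count", "id_score"])


def make_control_table(rows):
    """rows: (control_run, prey, count, id_score)"""
    return pd.DataFrame(rows, columns=["control_run", "prey", "count", "id_score"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
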