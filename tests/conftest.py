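import numpy as np
import pandas as pd
import pytest

from racebench import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def six_trial_table():
    """Minimal hand-written table covering all four modalities."""
    return pd.DataFrame(
        {
            "participant": ["p1"] * 6,
            "block": [1] * 6,
            "trial": [1, 2, 3, 4, 5, 6],
            "construction": ["simple"] * 6,
            "features": ["consistent"] * 6,
            "modality": ["A", "V", "AV", "catch", "A", "V"],
            "responded": [True, True, True, False, True, True],
            "rt_s": [0.31, 0.35, 0.27, None, 0.33, 0.36],
        }
    )


@pytest.fixture
def six_trial_csv(tmp_path, six_trial_table):
    path = tmp_path / "trials.csv"
    six_trial_table.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def simulated_table():
    """One simulated participant cell with a known switch cost."""
    return simulate_experiment(SimConfig(switch_cost=0.03, seed=11))
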