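import numpy as np
import pandas as pd
import pytest

from leadsync.synthetic import DyadSimConfig, simulate_dyad_motion


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)


@pytest.fixture
def uncoupled_dyad():
    return simulate_dyad_motion(DyadSimConfig(n_frames=250, coupling=0.0, seed=11))


@pytest.fixture
def coupled_dyad():
    return simulate_dyad_motion(
        DyadSimConfig(n_frames=250, coupling=0.8, influence_lag=12, seed=12)
    )


@pytest.fixture
def stimulus_predictors(rng):
    """One row per stimulus with the predictor columns the model expects."""
    n = 44
    return pd.DataFrame(
        {
            "stimulus_id": [f"s{i:02d}" for i in range(n)],
            "diagnosis": [i % 2 for i in range(n)],
            "green_leading_log": rng.normal(size=n),
            "white_leading_log": rng.normal(size=n),
            "motion_green": rng.normal(size=n),
            "motion_white": rng.normal(size=n),
            "source": [int(i < 24) for i in range(n)],
        }
    )
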