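import numpy as np
import pandas as pd
import pytest

import effortchoice as ec


@pytest.fixture(scope="session")
def eff_grid():
    return ec.build_effort_grid(n_repetitions=3, rng_seed=1)


@pytest.fixture(scope="session")
def fin_grid():
    return ec.build_financial_grid(n_repetitions=3, rng_seed=1)


@pytest.fixture(scope="session")
def hybrid():
    return ec.get_model("loss_aversion_encoding")


@pytest.fixture(scope="session")
def hybrid_choices(eff_grid, hybrid):
    """One simulated subject at the published effort-task median parameters."""
    rng = np.random.default_rng(42)
    return ec.simulate_choices(
        {"lam": 0.71, "gamma": 1.61, "mu": 0.064}, hybrid, eff_grid, rng
    )


@pytest.fixture
def tiny_choices():
    """Hand-sized effort trial table for exact likelihood checks."""
    return pd.DataFrame({
        "subject_id": ["s1"] * 6,
        "task": ["EFF"] * 6,
        "trial_index": range(6),
        "gain_pct": [-100, -50, 0, -20, -80, -10],
        "loss_pct": [0, 50, 100, 20, 80, 10],
        "response": [1, 1, 0, 0, 1, 0],
    })
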