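import warnings

import numpy as np
import pandas as pd
import pytest

from traitenv import GeneratorConfig, generate, preprocess
from traitenv.lmm_engine import ConvergenceWarning
from traitenv.model_design import random_design


@pytest.fixture(autouse=True)
def _quiet_convergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*fewer than 3 gas-exchange reps.*")
        yield


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic trial (405 plants, attrition injected)."""
    table, truth = generate(GeneratorConfig(seed=101))
    return table, truth


@pytest.fixture(scope="session")
def analysis_frame(default_table):
    table, _ = default_table
    df, report = preprocess(table)
    return df, report


@pytest.fixture(scope="session")
def nested_ids():
    """A small balanced nested id frame: 6 farms x 3 plots x 2 subplots x 2."""
    rows = [
        (f"F{f}", f"V{p}", f"S{s}", f"P{i}")
        for f in range(6) for p in range(3) for s in range(2) for i in range(2)
    ]
    return pd.DataFrame(rows, columns=["farm_id", "variety_id", "subplot_id", "plant_id"])


@pytest.fixture(scope="session")
def small_lmm(nested_ids):
    """Deterministic small mixed-model dataset with known structure."""
    rng = np.random.default_rng(42)
    df = nested_ids.copy()
    n = len(df)
    df["x1"] = rng.normal(size=n)
    df["x2"] = rng.normal(size=n)
    Z = random_design(df)
    y = (
        1.0
        + 0.5 * df["x1"].to_numpy()
        + Z[0] @ rng.normal(0, np.sqrt(0.5), Z[0].shape[1])
        + Z[1] @ rng.normal(0, np.sqrt(0.3), Z[1].shape[1])
        + Z[2] @ rng.normal(0, np.sqrt(0.2), Z[2].shape[1])
        + rng.normal(0, 0.7, n)
    )
    df["y"] = y
    return df, Z
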