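import numpy as np
import pandas as pd
import pytest

from pairbc import (
    SimConfig,
    assign_pairs,
    design_set,
    simulate_reference,
)


@pytest.fixture(scope="session")
def f_set():
    return design_set(4, seed=11, role="forward")


@pytest.fixture(scope="session")
def r_set():
    return design_set(8, seed=22, role="reverse")


@pytest.fixture(scope="session")
def sheet(f_set, r_set):
    cfg = SimConfig()
    return assign_pairs(f_set, r_set, cfg.sample_ids)


@pytest.fixture(scope="session")
def small_db():
    return simulate_reference(30, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_counts():
    """Deterministic 50-miRNA x 6-dataset raw count matrix."""
    gen = np.random.default_rng(99)
    base = gen.lognormal(3.0, 1.5, size=50)
    cols = {}
    for j in range(6):
        scale = 2.0 ** gen.normal(0, 1)
        cols[f"D{j + 1}"] = np.round(base * scale * gen.lognormal(0, 0.2, size=50))
    return pd.DataFrame(cols, index=[f"m{i:03d}" for i in range(50)])
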