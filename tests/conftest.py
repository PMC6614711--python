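import numpy as np
import pandas as pd
import pytest

from agsflow.containers import CommunityTable
from agsflow.simulate import SimConfig, generate_community_series


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_counts(rng):
    """20 samples x 50 taxa random count table."""
    values = pd.DataFrame(
        rng.integers(0, 200, size=(20, 50)),
        index=[f"s{i}" for i in range(20)],
        columns=[f"t{j}" for j in range(50)],
    )
    values.iloc[:, 0] += 1  # guard against an all-zero sample
    meta = pd.DataFrame({"reactor": "R1", "day": np.arange(20) * 7},
                        index=values.index)
    return CommunityTable(values, meta)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study, shared across tests (generation is
    deterministic, so sharing is safe)."""
    cfg = SimConfig(seed=7)
    tables, truth = generate_community_series(cfg)
    return cfg, tables, truth
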