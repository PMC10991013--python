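import numpy as np
import pandas as pd
import pytest

from vienna.datasets import item_reference_table
from vienna.simulate import default_vienna_profile, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 79), shared across tests."""
    return simulate_cohort(default_vienna_profile(seed=42))


@pytest.fixture(scope="session")
def reference_items():
    return item_reference_table()


@pytest.fixture(scope="session")
def reference_scores_matrix(reference_items):
    """A participants x items score matrix realizing the published per-item
    score frequencies (the joint arrangement across items is arbitrary)."""
    rng = np.random.default_rng(0)
    cols = {}
    for item, row in reference_items.iterrows():
        scores = np.repeat([0, 1, 2], [row.freq0, row.freq1, row.freq2])
        cols[item] = rng.permutation(scores)
    return pd.DataFrame(cols, index=[f"p{i:03d}" for i in range(79)])
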