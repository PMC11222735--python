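import numpy as np
import pandas as pd
import pytest

from scatpulse.config import default_config
from scatpulse.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced survey for fast end-to-end tests."""
    return default_config(n_individuals=12, scats_per_individual_per_season=2.0)


@pytest.fixture(scope="session")
def dataset(small_config):
    return simulate_dataset(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_scores(per_sample: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Long score table from {sample_id: {item: score}} (items absent from
    the mapping get 0)."""
    from scatpulse.config import FOOD_ITEMS

    rows = []
    for sid, items in per_sample.items():
        for item in FOOD_ITEMS:
            rows.append((sid, item, int(items.get(item, 0))))
        for item, score in items.items():
            if item not in FOOD_ITEMS:
                rows.append((sid, item, int(score)))
    return pd.DataFrame(rows, columns=["sample_id", "item", "score"])
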