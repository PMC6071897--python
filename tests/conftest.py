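import numpy as np
import pandas as pd
import pytest

from adipersist.adi import DEFAULT_INDICATORS
from adipersist.synthetic import SimConfig, analysis_cohort, simulate_study


def make_indicator_table(n=10, seed=0, constant=False):
    """Small random indicator table with valid structural columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"block_group_id": [f"BG{i:03d}" for i in range(n)]})
    pop = rng.integers(500, 3000, size=n)
    urban = (pop * rng.uniform(0.3, 1.0, size=n)).astype(int)
    df["population"] = pop
    df["urban_population"] = urban
    df["rural_population"] = pop - urban
    for name in DEFAULT_INDICATORS:
        df[name] = 1.0 if constant else rng.normal(size=n)
    return df


@pytest.fixture(scope="session")
def indicator_table():
    return make_indicator_table(n=40, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A modest default-config synthetic study shared across test modules."""
    return simulate_study(SimConfig(n_patients=4000, n_block_groups=100, seed=11))


@pytest.fixture(scope="session")
def small_cohort(small_study):
    return analysis_cohort(small_study)
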