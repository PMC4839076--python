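import numpy as np
import pandas as pd
import pytest

from vfrisk import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A small but structurally complete pooled survey table."""
    cfg = SimulationConfig(n_surveys=4, women_per_survey=2_500, seed=42)
    return simulate_population(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_match_table(rng, n=200, n_surveys=3, p_exposed=0.3, confounded=True):
    """Random analysis-like table for matching tests; exposed women are
    younger when ``confounded``, so matching has balance to recover."""
    exposed = rng.random(n) < p_exposed
    age = rng.integers(15, 50, n).astype(float)
    if confounded:
        age = np.where(exposed, np.clip(age - 8, 15, 49), age)
    return pd.DataFrame(
        {
            "survey_id": rng.choice([f"S{i}" for i in range(n_surveys)], n),
            "weight": rng.lognormal(0, 0.3, n),
            "age_years": age,
            "exposed": exposed,
            "outcome": rng.random(n) < 0.05,
        }
    )
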