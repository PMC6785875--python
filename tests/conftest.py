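import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microsurv.containers import FeatureTable, SurvivalData

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_survival() -> SurvivalData:
    """Twelve patients, half events, full covariate set."""
    rng = np.random.default_rng(42)
    n = 12
    frame = pd.DataFrame({
        "time": np.round(rng.uniform(1, 24, n), 1),
        "event": [1, 0] * (n // 2),
        "age": np.round(rng.normal(70, 10, n), 1),
        "sex": rng.integers(0, 2, n),
        "bmi": np.round(rng.normal(27, 4, n), 1),
        "stage": rng.integers(0, 2, n),
        "met_sites": rng.choice(["0", "1-2", ">=3"], n),
        "antibiotics": rng.integers(0, 2, n),
    }, index=[f"P{i:02d}" for i in range(n)])
    return SurvivalData(frame)


@pytest.fixture(scope="session")
def toy_counts() -> FeatureTable:
    values = pd.DataFrame(
        [[10, 0, 5, 5], [0, 8, 2, 10], [4, 4, 4, 8]],
        index=["s1", "s2", "s3"],
        columns=["fA", "fB", "fC", "fD"],
    )
    return FeatureTable(values, level="s-OTU")


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared across tests."""
    from microsurv.synthdata import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(seed=7))


def simulate_cox_data(seed, n, p, beta, baseline=0.05, cens_low=5, cens_high=40):
    """iid-normal covariate survival data with exponential PH event times."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    lp = X @ np.asarray(beta, dtype=float)
    t_event = rng.exponential(1.0 / (baseline * np.exp(lp)))
    censor = rng.uniform(cens_low, cens_high, n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return X, time, event
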