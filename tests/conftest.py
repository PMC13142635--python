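import numpy as np
import pandas as pd
import pytest

from canid.composite import CanidScorer
from canid.simulator import SimConfig, cohort_measures, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Moderate simulated cohort under default study conditions."""
    return simulate_cohort(SimConfig(n_dogs=80), seed=7)


@pytest.fixture(scope="session")
def merged(cohort):
    """Measures table merged with session covariates."""
    return cohort_measures(cohort)


@pytest.fixture(scope="session")
def fitted_scorer(merged):
    baseline = merged[merged["timepoint"] == "baseline"]
    return CanidScorer(random_state=11).fit(baseline)


@pytest.fixture(scope="session")
def scores(fitted_scorer, merged):
    return fitted_scorer.transform(merged)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_balanced_scores(n_dogs, icc, rng, n_tp=2, mean=0.0):
    """Balanced score table with known variance components (total var 1)."""
    tau = np.sqrt(icc)
    sig = np.sqrt(1.0 - icc)
    u = rng.normal(0, tau, n_dogs)
    tps = ["baseline", "m6", "m12"][:n_tp]
    rows = []
    for i in range(n_dogs):
        for tp in tps:
            rows.append({
                "dog_id": f"d{i}", "timepoint": tp,
                "overall_score": mean + u[i] + rng.normal(0, sig),
            })
    return pd.DataFrame(rows)
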