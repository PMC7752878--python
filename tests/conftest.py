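import numpy as np
import pandas as pd
import pytest

import survodds as so


@pytest.fixture(scope="session")
def exp_data():
    """Constant-hazard (exponential) survival data with admin censoring."""
    rng = np.random.default_rng(7)
    n = 1500
    t = rng.exponential(1 / 0.4, n)
    time = np.minimum(t, 3.0)
    event = t <= 3.0
    X = pd.DataFrame({"age_years": np.full(n, 65.0)})
    return X, so.survival_outcome(time, event), int(event.sum()), float(time.sum())


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort at reduced size."""
    return so.assemble_cohort(so.default_config(n=500, seed=42))


@pytest.fixture(scope="session")
def binary_ph_data():
    """Data simulated under exact proportional hazards with HR = 2 for a
    binary covariate (hazards 0.3 and 0.6 per year, censoring at 5 y)."""
    rng = np.random.default_rng(11)
    n = 4000
    female = rng.random(n) < 0.5
    lam = np.where(female, 0.6, 0.3)
    t = rng.exponential(1 / lam)
    time = np.minimum(t, 5.0)
    event = t <= 5.0
    X = pd.DataFrame(
        {
            "age_years": np.full(n, 65.0),
            "sex": np.where(female, "female", "male"),
        }
    )
    return X, so.survival_outcome(time, event)


def make_cohort(
    n=6,
    followup_days=(30, 100, 2000, 1826, 90, 50),
    dead=(1, 1, 0, 1, 1, 1),
    cancer_death=(0, 1, 0, 1, 1, 1),
    ages=(55.0, 72.0, 66.0, 80.0, 69.99, 75.0),
):
    """Small hand-built cohort in the analysis schema."""
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "age_years": list(ages)[:n],
            "sex": ["male"] * n,
            "education": ["<=9"] * n,
            "cci": ["0"] * n,
            "neoadjuvant": ["no"] * n,
            "histology": ["adenocarcinoma"] * n,
            "stage": ["0-II"] * n,
            "margin": ["R0"] * n,
            "followup_days": list(followup_days)[:n],
            "dead": list(dead)[:n],
            "cancer_death": list(cancer_death)[:n],
        }
    )


@pytest.fixture
def tiny_cohort():
    return make_cohort()
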