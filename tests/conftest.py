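"""Shared fixtures: small synthetic cohorts and frame builders."""
import numpy as np
import pandas as pd
import pytest

from sepsisbench.config import CohortConfig
from sepsisbench.synth import generate_cohort


def obs_frame(rows, admission_id="A1"):
    """rows: (time_min, element, value) triples."""
    return pd.DataFrame(
        [(admission_id, int(t), e, float(v)) for t, e, v in rows],
        columns=["admission_id", "time_min", "element", "value"])


def orders_frame(rows, admission_id="A1"):
    """rows: (time_min, kind, detail) triples."""
    return pd.DataFrame(
        [(admission_id, int(t), k, d) for t, k, d in rows],
        columns=["admission_id", "time_min", "kind", "detail"])


def dx_frame(rows, admission_id="A1"):
    """rows: (code, time_min) pairs."""
    return pd.DataFrame(
        [(admission_id, c, int(t)) for c, t in rows],
        columns=["admission_id", "code", "time_min"])


def admission_row(admission_id="A1", los_min=10 * 1440, disposition="home",
                  **kw):
    base = {"admission_id": admission_id, "patient_id": "P1",
            "admit_min": 0, "discharge_min": int(los_min), "age": 60,
            "sex": "female", "race_ethnicity": "white", "site": "tertiary",
            "service": "medicine", "source": "ED", "disposition": disposition}
    base.update(kw)
    return pd.Series(base)


@pytest.fixture(scope="session")
def small_cohort():
    """~120 admissions at realistic prevalence; exercises all event kinds."""
    return generate_cohort(CohortConfig(n_admissions=120, seed=5))


@pytest.fixture(scope="session")
def enriched_cohort():
    """Sepsis-enriched cohort so sepsis-only analyses have decent n."""
    return generate_cohort(CohortConfig(
        n_admissions=260, sepsis_prevalence=0.30, seed=17))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
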