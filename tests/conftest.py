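"""Shared fixtures: tiny hand-built cohorts and quiet logging."""

import logging

import numpy as np
import pandas as pd
import pytest

from acce.propensity import Cohort


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("acce").setLevel(logging.WARNING)
    yield


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    """10 subjects, binary IV with known arm prevalences (treated 4/5=0.8,
    comparison 1/5=0.2) and a continuous covariate."""
    return pd.DataFrame({
        "t": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        "y": [1, 0, 1, 0, 0, 1, 0, 0, 0, 0],
        "z": [1, 1, 1, 1, 0, 0, 0, 0, 0, 1],
        "x": [0.5, -0.2, 1.1, 0.0, 0.3, -0.5, 0.2, -1.0, 0.1, 0.4],
    })


@pytest.fixture
def toy_cohort(toy_frame) -> Cohort:
    return Cohort.from_dataframe(toy_frame, treatment="t", outcome="y",
                                 covariates=["x", "z"], iv_columns=("z",))


def make_two_arm_cohort(n_treated: int, events_treated: int,
                        n_comparison: int, events_comparison: int,
                        rng: np.random.Generator | None = None) -> Cohort:
    """Deterministic cohort with exact arm sizes and event counts and a
    noise covariate."""
    rng = rng or np.random.default_rng(0)
    t = np.r_[np.ones(n_treated), np.zeros(n_comparison)].astype(int)
    y = np.r_[np.ones(events_treated), np.zeros(n_treated - events_treated),
              np.ones(events_comparison), np.zeros(n_comparison - events_comparison)].astype(int)
    df = pd.DataFrame({"t": t, "y": y, "x": rng.standard_normal(len(t))})
    return Cohort.from_dataframe(df, treatment="t", outcome="y", covariates=["x"])
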