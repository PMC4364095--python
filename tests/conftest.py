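"""Shared fixtures: tiny hand-built event tables and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from weibmix import (
    EventTable,
    ParameterSet,
    build_model_frame,
    simple_config,
    simulate_cohort,
)


@pytest.fixture
def stroke_angina_table():
    """One subject: stroke at day 10 and day 100, angina at day 150, one
    follow-up year; a second, event-free subject anchors the type universe."""
    rec = pd.DataFrame(
        {
            "subject_id": ["a", "a", "a"],
            "event_type": ["stroke", "stroke", "angina"],
            "occurrence_index": [1, 2, 1],
            "time": [10 / 365, 100 / 365, 150 / 365],
            "status": [1, 1, 1],
        }
    )
    cov = pd.DataFrame({"x": [1.0, 0.0]}, index=pd.Index(["a", "b"], name="subject_id"))
    fu = pd.Series([1.0, 1.0], index=cov.index)
    return EventTable(records=rec, covariates=cov, followup_end=fu)


@pytest.fixture
def three_subject_frames():
    """Small recurrent multi-type table and its four frames, for oracle checks."""
    rec = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s1", "s2", "s3"],
            "event_type": ["mi", "mi", "stroke", "stroke", "mi"],
            "occurrence_index": [1, 2, 1, 1, 1],
            "time": [0.8, 2.5, 1.9, 3.1, 0.4],
            "status": [1, 1, 1, 1, 1],
        }
    )
    cov = pd.DataFrame(
        {"x": [1.0, 0.0, 1.0], "z": [0.2, -0.5, 1.1]},
        index=pd.Index(["s1", "s2", "s3"], name="subject_id"),
    )
    fu = pd.Series([5.0, 4.0, 6.0], index=cov.index)
    table = EventTable(records=rec, covariates=cov, followup_end=fu)
    return {kind: build_model_frame(table, kind) for kind in ("m1", "m2", "m3", "m4")}


@pytest.fixture
def fixture_params():
    """Per-kind parameter sets on the same beta, for the oracle fixtures."""
    common = dict(beta0=-1.0, beta=pd.Series({"x": 0.5, "z": -0.3}))
    return {
        "m1": ParameterSet(**common, shape=1.2),
        "m2": ParameterSet(**common, shape=1.2, sd_recurrent=0.6),
        "m3": ParameterSet(**common, shape=np.array([1.2, 0.8]), sd_type=0.6),
        "m4": ParameterSet(**common, shape=np.array([1.2, 0.8]),
                           sd_subject_type=0.5, sd_subject=0.7),
    }


@pytest.fixture(scope="session")
def m2_cohort():
    cfg = simple_config("m2", n_subjects=400, seed=7, beta0=-2.5, beta_x=0.5,
                        shape=1.2, sd=0.8)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def m4_cohort():
    cfg = simple_config("m4", n_subjects=400, seed=11, beta0=-3.8, beta_x=0.6,
                        sd=0.8, sd_subject_type=0.5)
    return simulate_cohort(cfg)
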