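"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import numpy as np
import pytest

from edafaa.features import build_feature_table
from edafaa.synthetic import SessionConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """Two participants, one task, 12 short trials, strong coupling."""
    cfg = SessionConfig(n_participants=2, tasks=("EAT",), n_trials=12,
                        trial_duration_s=90.0, coupling_kappa=0.9, seed=42)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_table(small_session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(small_session)


@pytest.fixture(scope="session")
def null_session():
    """Uncoupled (kappa = 0) cohort for null-calibration checks."""
    cfg = SessionConfig(n_participants=1, tasks=("EAT",), n_trials=12,
                        trial_duration_s=90.0, coupling_kappa=0.0, seed=43)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def null_table(null_session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(null_session)
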