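"""Shared fixtures: small synthetic cohorts and reusable fitted models."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gammastates.preprocess import bandpass, extract_baselines, zscore_concatenate
from gammastates.simulate import CohortConfig, default_state_specs, generate_cohort


def small_cohort_config(seed: int = 11, **overrides) -> CohortConfig:
    """A desk-scale cohort: 5 subjects, 8 parcels, 10 trials, no rest."""
    defaults = dict(
        n_subjects=5,
        n_parcels=8,
        n_trials=10,
        rest_duration_s=0.0,
        roi_parcels=(6, 7),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_concat(small_cohort):
    recs = []
    for sub in small_cohort.subjects:
        ts = bandpass(sub.task, 1.0, 35.0)
        recs.append(extract_baselines(ts, sub.events, 1.0))
    return zscore_concatenate(recs)


@pytest.fixture(scope="session")
def fitted_small(small_cohort, small_concat):
    from gammastates.hmm import TDEHMM

    model = TDEHMM(small_concat, n_states=4, n_lags=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(max_iter=40, n_restarts=2, seed=0)
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
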