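"""Shared fixtures: a small simulated cohort, matched and binned once per
session so the scan tests don't repeat the expensive setup."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import otcscan as o

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_cfg() -> o.SimConfig:
    return o.SimConfig(n_cases=30, n_controls=90, seed=11,
                       missingness={"household_size": 0.05, "bmi": 0.1,
                                    "oc_years": 0.1})


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    roster, log, gt = o.simulate_cohort(small_cfg)
    return roster, log, gt


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    roster, log, _ = small_cohort
    eligible, _ = o.apply_exclusions(roster)
    sets, _ = o.match(eligible, ratio=2)
    o.align_all(sets, eligible)
    panel = o.bin_monthly(log, sets,
                          known_participants=set(roster["participant_id"]))
    return panel, eligible, sets


def make_strata(rng: np.random.Generator, n_strata: int, beta: np.ndarray,
                stratum_size: int = 3):
    """Simulate 1:(size−1) matched strata under the conditional model:
    covariates N(0,1); the case slot is drawn with probability softmax(x·β)."""
    k = len(beta)
    X = rng.normal(size=(n_strata, stratum_size, k))
    eta = X @ beta
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((n_strata, 1))
    case_slot = (p.cumsum(axis=1) < u).sum(axis=1)
    endog = np.zeros((n_strata, stratum_size))
    endog[np.arange(n_strata), case_slot] = 1
    groups = np.repeat(np.arange(n_strata), stratum_size)
    return endog.ravel(), X.reshape(-1, k), groups
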