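"""Shared fixtures.

The expensive object here is ``recovery_runs``: five seeded replicates of
the full parameter-recovery pipeline (simulate at known parameters, fit by
MCMC) at the scaled-down study conditions. It is session-scoped and shared
between the acceptance checks (coverage, convergence) and the pipeline
closure/calibration tests so the simulation cost is paid once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import compclass as cc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> cc.DegreeGrid:
    return cc.DegreeGrid.default()


@pytest.fixture(scope="session")
def unit_normal(grid) -> cc.DegreeDistribution:
    return cc.make_gaussian_prior(0.0, 1.0, grid, label="superordinate")


@pytest.fixture()
def basketball_hyp(grid, unit_normal) -> cc.ClassHypothesis:
    """The height walkthrough: subordinate N(0.5, 0.5) vs. superordinate N(0, 1)."""
    sub = cc.make_gaussian_prior(0.5, 0.5, grid, label="basketball player")
    return cc.ClassHypothesis(sub, unit_normal, prior=0.5)


@dataclass
class RecoveryRun:
    theta_true: cc.ParameterVector
    data: cc.BehavioralDataset
    results: "cc.ComparisonClassResults"


# generating global parameters for the recovery study
RECOVERY_GLOBALS = {
    "alpha1": 1.5,
    "alpha2": 5.0,
    "beta00": -0.1,
    "beta01": 1.6,
    "beta1": 0.2,
}
RECOVERY_N_SETS = 20
RECOVERY_N_PER_CELL = 200
RECOVERY_CHAINS = 3
RECOVERY_ITERS = 20_000
N_REPLICATES = 5


def _one_recovery(replicate: int) -> RecoveryRun:
    design = cc.make_item_design(RECOVERY_N_SETS, seed=100 + replicate)
    theta = cc.default_theta(design, **RECOVERY_GLOBALS)
    data = cc.simulate_dataset(
        design,
        theta,
        n_cc_per_cell=RECOVERY_N_PER_CELL,
        n_endorse_per_cell=RECOVERY_N_PER_CELL,
        seed=200 + replicate,
    )
    model = cc.ComparisonClassModel(data, variant="basic_freq")
    res = model.fit(
        n_chains=RECOVERY_CHAINS,
        n_iter=RECOVERY_ITERS,
        seed=300 + replicate,
        thin=5,
    )
    return RecoveryRun(theta_true=theta, data=data, results=res)


_RECOVERY_CACHE: dict[int, RecoveryRun] = {}


def _cached_recovery(replicate: int) -> RecoveryRun:
    if replicate not in _RECOVERY_CACHE:
        _RECOVERY_CACHE[replicate] = _one_recovery(replicate)
    return _RECOVERY_CACHE[replicate]


@pytest.fixture(scope="session")
def recovery_runs() -> list[RecoveryRun]:
    return [_cached_recovery(r) for r in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def recovery_run() -> RecoveryRun:
    return _cached_recovery(0)
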