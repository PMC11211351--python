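import numpy as np
import pytest

from warfinr import (
    CohortSpec,
    DEFAULT_THETA,
    sample_cohort,
    simulate_observations,
)
from warfinr.experiments import recovery_experiment


@pytest.fixture(scope="session")
def theta():
    return DEFAULT_THETA


@pytest.fixture(scope="session")
def small_sim():
    """A 40-subject simulated cohort at the default (published) parameters."""
    patients = sample_cohort(CohortSpec(n_subjects=40, seed=7))
    return simulate_observations(patients, DEFAULT_THETA, omega=0.558,
                                 sigma=0.365, seed=8)


@pytest.fixture(scope="session")
def patient(small_sim):
    """One subject with a full dosing history and observations."""
    return small_sim.patients[0]


@pytest.fixture(scope="session")
def recovery_runs():
    """Reference parameter-recovery experiment: ten replicate 200-subject
    cohorts simulated at the published parameters and refit by Laplace from
    perturbed starting values.  Shared by the recovery-invariant test and the
    acceptance test for the same experiment."""
    return recovery_experiment(seed=20240627, n_subjects=200,
                               n_replicates=10, compute_rse=True,
                               effort="fast")
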