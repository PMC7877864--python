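"""Shared fixtures: nominal model objects and small seeded populations."""

from __future__ import annotations

import numpy as np
import pytest

from ibdqsp import CrohnsQSPModel
from ibdqsp.network import build_network
from ibdqsp.params import design_state_vector, nominal_parameters
from ibdqsp.population import Cohort, VirtualPatient, generate_cohort
from ibdqsp.species import IDX, N_SPECIES
from ibdqsp.synthetic import make_paper_defaults


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def design_vec():
    return design_state_vector()


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def model():
    return CrohnsQSPModel()


@pytest.fixture(scope="session")
def paper_defaults():
    return make_paper_defaults()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but real cohort (steady states solved per patient)."""
    return generate_cohort(n=60, seed=11)


@pytest.fixture(scope="session")
def fabricated_cohort(nominal):
    """A large cohort with fabricated lognormal baselines (no ODE solves).

    Used where a test needs many patients with a known baseline law but the
    mechanistic steady state is irrelevant (selection statistics etc.).
    """
    rng = np.random.default_rng(42)
    n = 5000
    log_crp = rng.normal(np.log(10.0), np.log(2.5), n)
    log_fcp = 0.6 * (log_crp - np.log(10.0)) + np.log(600.0) \
        + rng.normal(0.0, 0.5, n)
    patients = []
    for i in range(n):
        baseline = np.zeros(N_SPECIES)
        baseline[IDX["CRP"]] = np.exp(log_crp[i])
        baseline[IDX["FCP"]] = np.exp(log_fcp[i])
        patients.append(VirtualPatient(id=i, parameters=nominal,
                                       baseline=baseline))
    return Cohort(patients=patients, seed=42, notes="fabricated baselines")
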