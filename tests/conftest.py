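"""Shared fixtures: reference models, synthetic cohorts, toy subjects."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from valpop import (
    CohortConfig,
    Observation,
    Regimen,
    Subject,
    fit,
    generate_cohort,
)
from valpop.datasets import base_model, final_model

logging.getLogger("valpop").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def final_model_spec():
    return final_model()


@pytest.fixture(scope="session")
def base_model_spec():
    return base_model()


@pytest.fixture(scope="session")
def study_cohort():
    """One default-condition synthetic cohort (103 subjects, ~376 troughs)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort for tests where speed matters more than power."""
    return generate_cohort(CohortConfig(n_subjects=40), seed=11)


@pytest.fixture(scope="session")
def final_fit(final_model_spec, study_cohort):
    """The final model refit to the default synthetic cohort."""
    return fit(final_model_spec, study_cohort, compute_rse=False)


@pytest.fixture
def toy_subject():
    return Subject(
        id="T1",
        age_y=5.0,
        weight_kg=20.0,
        genotypes={"rs3789243": "AA"},
        regimen=Regimen(dose_mg=250.0, tau_h=12.0),
    )


def make_observations(subject, concs, t=None):
    t = subject.regimen.tau_h if t is None else t
    return [Observation(subject.id, t, c) for c in np.atleast_1d(concs)]
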