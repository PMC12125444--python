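"""Shared fixtures: the study framing protocol, a default synthetic input
function, a representative medial-temporal subject, and seeded cohorts.

Session scope keeps the expensive cohort generations to one per run."""

import numpy as np
import pytest

import petkin as pk
from petkin.synthetic import CohortSpec, InputModel, generate_cohort, generate_input

COHORT_SEED = 11

# Cohort-mean 2TCM parameters per ROI (the generative defaults' centers).
MT_MEANS = dict(vb=0.038, K1=0.271, k2=0.190, k3=0.039, k4=0.070, delay=3.766)
LP_MEANS = dict(vb=0.029, K1=0.372, k2=0.245, k3=0.031, k4=0.083, delay=4.625)
PC_MEANS = dict(vb=0.037, K1=0.369, k2=0.253, k3=0.031, k4=0.076, delay=4.323)


@pytest.fixture(scope="session")
def schedule():
    return pk.parse_frame_schedule(pk.DEFAULT_PROTOCOL)


@pytest.fixture(scope="session")
def default_ifs(schedule):
    return generate_input(InputModel(), schedule)


@pytest.fixture(scope="session")
def mt_truth():
    return pk.TwoTissueParams(**MT_MEANS)


@pytest.fixture(scope="session")
def mt_tac(mt_truth, default_ifs, schedule):
    """Noiseless representative medial-temporal tissue curve."""
    return pk.solve_2tcm(mt_truth, default_ifs, schedule, label="medial_temporal")


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(CohortSpec(n_subjects=15, noise_scale=0.0, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def noisy_cohort():
    return generate_cohort(CohortSpec(n_subjects=15, noise_scale=0.05, seed=COHORT_SEED))
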