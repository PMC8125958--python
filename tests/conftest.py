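"""Shared fixtures: small cohorts, rendered image pairs, noise-free configs."""

from dataclasses import replace

import numpy as np
import pytest

import ricefusion as rf


@pytest.fixture(scope="session")
def default_cohort():
    return rf.generate_cohort(rf.CohortConfig())


@pytest.fixture(scope="session")
def sensitivity():
    return rf.default_sensitivity()


@pytest.fixture(scope="session")
def noiseless_sensitivity(sensitivity):
    return replace(sensitivity, spot_noise_sd=0.0, sample_effect_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_signature():
    return replace(
        rf.default_signature(),
        scatter_mult_sd=0.0,
        scatter_add_sd=0.0,
        noise_sd=0.0,
        sample_effect_sd=0.0,
    )


@pytest.fixture(scope="session")
def rendered_pair(default_cohort, noiseless_sensitivity):
    """A noise-free before/after pair plus the programmed colour shifts."""
    sample = default_cohort[10]
    before, after = rf.render_sensor_pair(
        sample, noiseless_sensitivity, seed=99
    )
    programmed = noiseless_sensitivity.coefficients * sample.fatty_acid
    return before, after, programmed


@pytest.fixture(scope="session")
def small_experiment_config():
    """A reduced experiment: 4 months x 8 samples, short PC scan, few runs."""
    return rf.ExperimentConfig(
        cohort=rf.CohortConfig(n_months=4, samples_per_month=8, seed=5),
        k_range=(1, 2, 3),
        n_runs=3,
        folds=4,
        seed=17,
    )
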