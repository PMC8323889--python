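"""Shared fixtures: small synthetic cohorts and a trained toy embedding.

Expensive artifacts (cohorts, one trained autoencoder) are session-scoped so
many tests can interrogate the same objects.
"""

import numpy as np
import pytest

from shapeincome.autoencoder import EncoderSpec, GraphicalAutoencoder, TrainConfig
from shapeincome.meshes import flatten_cohort
from shapeincome.synthetic import CohortConfig, generate_cohort, make_template_mesh


@pytest.fixture(scope="session")
def male_template():
    return make_template_mesh("male", 16, 12)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed-gender cohort, n=300, default noise."""
    return generate_cohort(CohortConfig(n_subjects=300, seed=7))


@pytest.fixture(scope="session")
def male_cohort():
    """All-male cohort (two active shape factors), n=400."""
    return generate_cohort(CohortConfig(n_subjects=400, seed=11, male_fraction=1.0))


@pytest.fixture(scope="session")
def female_cohort():
    """All-female cohort (three active shape factors), n=400."""
    return generate_cohort(CohortConfig(n_subjects=400, seed=13, male_fraction=0.0))


@pytest.fixture(scope="session")
def trained_male_embedding(male_cohort):
    """A d=2 autoencoder trained on the male cohort; reused by many tests."""
    ds = flatten_cohort(male_cohort.meshes, center=True, scale=True)
    spec = EncoderSpec(ds.n_inputs, 2, (64, 32, 16))
    cfg = TrainConfig(epochs=300, batch_size=100, seed=5)
    return ds, GraphicalAutoencoder(ds, spec, cfg).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
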