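"""Shared fixtures: small synthetic cohorts and trained models.

Heavy artifacts are session-scoped so the planted-effect cohort, its
autoencoder, and its latents are built once and reused across test modules.
"""

import numpy as np
import pytest

from dbmorph.autoencoder import encode_batch, train_autoencoder
from dbmorph.classifier import stratified_split
from dbmorph.synthetic import generate_cohort, strong_regions

SMALL_DIMS = (24, 28, 24)  # latent grid (3, 3, 3) after three halvings


@pytest.fixture(scope="session")
def strong_cohort():
    """48+48 subjects with a strong planted effect: large spheres, shift 0.6
    (several times the smoothed subject-field standard deviation)."""
    return generate_cohort(n_cases=48, n_controls=48, dims=SMALL_DIMS,
                           regions=strong_regions(SMALL_DIMS), seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """Same conditions but zero planted effect: labels carry no image signal."""
    regions = strong_regions(SMALL_DIMS, group_shift=0.0)
    return generate_cohort(n_cases=48, n_controls=48, dims=SMALL_DIMS,
                           regions=regions, seed=12)


@pytest.fixture(scope="session")
def strong_ae(strong_cohort):
    """Autoencoder trained briefly on the strong cohort (enough to encode
    the planted signal; full convergence is exercised elsewhere)."""
    split = stratified_split(strong_cohort, test_ratio=0.2, seed=11)
    ae, trace = train_autoencoder(strong_cohort.volume_array(), split,
                                  steps=600, seed=11)
    return ae, trace, split


@pytest.fixture(scope="session")
def strong_latents(strong_cohort, strong_ae):
    ae, _, _ = strong_ae
    return encode_batch(ae, strong_cohort.volume_array())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
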