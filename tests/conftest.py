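"""Shared fixtures: tiny phantom cohorts and a trained autoencoder.

Everything is generated programmatically at test time; session scope
keeps the expensive artifacts (autoencoder training) to one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirhsi import (
    AutoencoderConfig,
    PhantomConfig,
    aggregate_features,
    encode_patches,
    extract_patches,
    features_table,
    generate_cohort,
    preprocess,
    train_autoencoder,
)

TINY = dict(height=24, width=24, bands=12, effect_size=6.0, noise_sd=0.05)
TINY_AE = dict(latent_dim=16, epochs=6, batch_size=128)


def make_cohort(n=12, seed=0, **overrides):
    """Small preprocessed phantom cohort."""
    params = {**TINY, **overrides}
    cubes, labels = generate_cohort(PhantomConfig(n_samples=n, seed=seed, **params))
    return [preprocess(c) for c in cubes], labels


def cohort_features(cubes, seed=0, **ae_overrides):
    """Patch -> tiny autoencoder -> global feature table."""
    psets = [extract_patches(c) for c in cubes]
    pool = np.concatenate([p.patches for p in psets])
    rng = np.random.default_rng(seed)
    if pool.shape[0] > 1500:
        pool = pool[np.sort(rng.choice(pool.shape[0], 1500, replace=False))]
    model = train_autoencoder(
        pool, AutoencoderConfig(seed=seed, **{**TINY_AE, **ae_overrides})
    )
    embs = [encode_patches(model, p) for p in psets]
    return features_table([aggregate_features(e) for e in embs]), model, embs


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_cohort(n=12, seed=0)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    cubes, labels = tiny_cohort
    feats, model, embs = cohort_features(cubes, seed=0)
    return feats, labels, model, embs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
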