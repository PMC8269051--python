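"""Shared fixtures.

The expensive resource is the desk-scale trained IAE; it is trained at
most once per seed per session and shared across model, latent-ops,
signature and acceptance tests.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from tumorsig import phantom, pipeline, preprocess


@lru_cache(maxsize=3)
def trained_pipeline(seed: int):
    """(bundle, history, patches, labels) of the desk-scale phantom run."""
    return pipeline.train_phantom_iae(seed=seed)


@pytest.fixture(scope="session")
def desk_run():
    return trained_pipeline(0)


@pytest.fixture(scope="session")
def trained_bundle(desk_run):
    return desk_run[0]


@pytest.fixture(scope="session")
def phantom_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def small_patch_set(phantom_spec):
    """40 normalized phantom patches (20 per class) with masks and labels."""
    hu, masks, labels = phantom.generate_dataset(phantom_spec, 20, 20, seed=7)
    return preprocess.clip_and_scale(hu), masks, labels
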