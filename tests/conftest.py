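"""Shared fixtures: phantoms, trained models and end-to-end pipeline runs.

The expensive end-to-end run (default phantom, 10⁴ training samples per
class) is computed once per session and shared by the recovery and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import gliotype
from gliotype import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def small_spec():
    """A coarse, fast phantom for unit tests that only need plausible data."""
    return phantom.PhantomSpec(shape=(64, 64, 10), voxel_size=(3.75, 3.75, 10.0), seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    volume, truth, volumes_ml = phantom.generate_phantom(small_spec)
    return {"spec": small_spec, "volume": volume, "truth": truth, "volumes_ml": volumes_ml}


@pytest.fixture(scope="session")
def trained_pdds(small_spec):
    """PDDs trained on 10⁴ draws per class from the small phantom's models."""
    train = phantom.sample_training_set(small_spec, 10_000)
    return gliotype.build_all_pdds(train)


@pytest.fixture(scope="session")
def e2e():
    """Full end-to-end pipeline run on the default phantom (seed 1)."""
    spec = phantom.PhantomSpec(seed=1)
    volume, truth, volumes_ml = phantom.generate_phantom(spec)
    train = phantom.sample_training_set(spec, 10_000)
    model = gliotype.TissueTypeModel.from_training_samples(
        volume, train, brain_mask=truth.labels > 0
    )
    results = model.fit()
    return {
        "spec": spec,
        "volume": volume,
        "truth": truth,
        "volumes_ml": volumes_ml,
        "model": model,
        "results": results,
    }


@pytest.fixture(scope="session")
def e2e_lowgrade():
    """End-to-end run on a phantom containing no high-grade tissue."""
    spec = phantom.pure_lowgrade_spec(
        seed=2, shape=(96, 96, 16), voxel_size=(2.5, 2.5, 6.25)
    )
    volume, truth, volumes_ml = phantom.generate_phantom(spec)
    train = phantom.sample_training_set(spec, 10_000)
    results = gliotype.TissueTypeModel.from_training_samples(
        volume, train, brain_mask=truth.labels > 0
    ).fit()
    return {"spec": spec, "truth": truth, "volumes_ml": volumes_ml, "results": results}
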