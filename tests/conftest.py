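"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from flatfoot.phantom import PhantomSpec, generate_phantom, sample_dataset, build_templates
from flatfoot.pipeline import FlatFootDiagnoser


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_normal():
    """One clean normal-foot phantom with exact ground truth."""
    return generate_phantom(PhantomSpec(target_class="normal", seed=7))


@pytest.fixture(scope="session")
def phantom_noiseless():
    """Explicit angles, no blur or noise: a piecewise-constant render."""
    return generate_phantom(
        PhantomSpec(target_class=None, angles=(25.0, 158.0, 2.0), noise_sd=0.0, blur_sd=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Six phantoms (two per class), the training side of small pipeline tests."""
    dataset, manifest = sample_dataset({"normal": 2, "mild": 2, "moderate": 2}, seed=4242)
    return dataset, manifest


@pytest.fixture(scope="session")
def template_library(small_dataset):
    dataset, _ = small_dataset
    return build_templates(dataset)


@pytest.fixture(scope="session")
def fitted_diagnoser(small_dataset):
    dataset, _ = small_dataset
    return FlatFootDiagnoser(max_templates_per_poi=None).fit(dataset)
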