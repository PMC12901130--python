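"""Shared fixtures: phantoms are expensive, so the heavier ones are
session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from flairqc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Degradation-free phantom at the default 128^3 / 2 mm configuration."""
    spec = PhantomSpec(seed=11)
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def sharp_phantom():
    """Zero-blur, noise-free phantom rasterized at 4x for edge analysis."""
    spec = PhantomSpec(
        matrix_size=(96, 96, 96),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        supersample=4,
        seed=21,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def gauss_phantom():
    """Noise-free phantom with isotropic 1 mm Gaussian blur (2 mm voxels)."""
    sigma = 1.0
    spec = PhantomSpec(
        matrix_size=(96, 96, 96),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        supersample=4,
        blur_fwhm_mm=(sigma * 2.3548200,) * 3,
        seed=22,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def biased_phantom():
    """Noise-free phantom with a 20% multiplicative bias field."""
    spec = PhantomSpec(
        matrix_size=(96, 96, 96),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        supersample=2,
        bias_amplitude=0.2,
        seed=23,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
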