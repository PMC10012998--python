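"""Shared fixtures: small synthetic scenes and movies built once per session."""

import numpy as np
import pytest

from cardialt import alternans, ffi, synthdata


@pytest.fixture(scope="session")
def da_scene():
    """Two antiphase 2:2 regions at 8 Hz, 4 s, mild noise."""
    return synthdata.two_region_scene(ny=64, nx=64, pacing_hz=8.0,
                                      apd_base=70.0, apd_delta=20.0,
                                      duration_s=4.0, noise_sigma=0.02,
                                      seed=1)


@pytest.fixture(scope="session")
def da_movie(da_scene):
    return synthdata.generate_movie(da_scene)


@pytest.fixture(scope="session")
def da_movie_pre(da_movie):
    return alternans.preprocess_movie(da_movie)


@pytest.fixture(scope="session")
def da_region_masks(da_scene):
    """Interior (non-nodal-band) masks of the two antiphase regions."""
    labels = da_scene.region_labels
    cols = np.arange(da_scene.nx)[None, :] * np.ones((da_scene.ny, 1))
    far = np.abs(cols - da_scene.nx / 2 + 0.5) > 8
    return (labels == 0) & far, (labels == 1) & far


@pytest.fixture(scope="session")
def da_fourier(da_movie):
    return ffi.ffi_transform(da_movie, window=(0, da_movie.n_frames))
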