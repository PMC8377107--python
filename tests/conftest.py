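"""Shared fixtures: tiny grids, protocols and phantoms for fast unit tests."""

import numpy as np
import pytest

from spectquant.phantoms import VoxelGrid, make_point_source
from spectquant.presets import get_preset
from spectquant.projector import ModelFlags, Protocol


@pytest.fixture
def tiny_grid():
    """32^3 grid at 19.2 mm: same physical extent as the clinical 128^3."""
    return VoxelGrid((32, 32, 32), 19.2)


@pytest.fixture
def tiny_protocol():
    return Protocol(n_views=12, time_per_view=40.0, detector_bins=(32, 32),
                    bin_size=19.2)


@pytest.fixture
def reduced_grid():
    return VoxelGrid((64, 64, 64), 9.6)


@pytest.fixture
def reduced_protocol():
    return Protocol(n_views=30, time_per_view=40.0, detector_bins=(64, 64),
                    bin_size=9.6)


@pytest.fixture(params=["I123_LEHR", "I123_ME", "I131_HE"])
def any_camera(request):
    return get_preset(request.param)


@pytest.fixture
def camera_me():
    return get_preset("I123_ME")


@pytest.fixture
def all_flags():
    return ModelFlags(attenuation=True, cdr=True, scatter=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
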