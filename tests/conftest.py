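"""Shared fixtures: small geometries and one desk-scale synthetic subject."""

import numpy as np
import pytest

from bromeg.headmodel import build_sensor_array, build_source_grid, compute_leadfield
from bromeg.simulate import RecordingConfig, generate_recording

CONDUCTOR_R = 0.09


@pytest.fixture(scope="session")
def sensor_array():
    return build_sensor_array(n_chan=32, helmet_radius=0.11, baseline=0.05, seed=0)


@pytest.fixture(scope="session")
def source_grid():
    return build_source_grid(spacing=0.025, shell_radius=0.07,
                             conductor_radius=CONDUCTOR_R)


@pytest.fixture(scope="session")
def leadfield(sensor_array, source_grid):
    return compute_leadfield(sensor_array, source_grid, CONDUCTOR_R)


@pytest.fixture(scope="session")
def small_config():
    """Short desk-scale recording: full signal/noise levels, ~20 blinks."""
    return RecordingConfig.desk_scale(duration=150.0)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
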