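import h5py
import numpy as np
import pytest

from managedh5 import (
    ImageMapParams,
    SessionParams,
    generate_ephys_session,
    generate_image_scaling_fixture,
)


@pytest.fixture
def small_session_params():
    return SessionParams(
        n_grid_electrodes=6,
        n_poly_electrodes=3,
        sampling_rate=200.0,
        frequencies_khz=(0.5, 32.0),
        attenuations_db=(0.0,),
        repetitions=2,
        stimulus_duration_ms=50.0,
        seed=7,
    )


@pytest.fixture
def session_path(tmp_path, small_session_params):
    path = str(tmp_path / "session.h5")
    handle = generate_ephys_session(small_session_params, path)
    handle.close()
    return path


@pytest.fixture
def small_image_params():
    return ImageMapParams(rows=10, cols=12, factor=3, seed=3)


@pytest.fixture
def image_path(tmp_path, small_image_params):
    path = str(tmp_path / "image.h5")
    h5 = generate_image_scaling_fixture(small_image_params, path)
    h5.close()
    return path


@pytest.fixture
def image_file(image_path):
    with h5py.File(image_path, "r+") as h5:
        yield h5
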