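import numpy as np
import pytest

import fmip


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def strong_model():
    return fmip.BiosensorModel("BS1", "strong")


@pytest.fixture
def egf_condition():
    return fmip.ConditionSpec("egf", (("EGF", 100.0),),
                              stimulation_time=30.0)


@pytest.fixture
def time_grid():
    return np.arange(0.0, 150.0 + 1e-9, 3.0)


def noiseless_camera():
    return fmip.CameraModel(read_noise_sd=0.0, quantize=False)


@pytest.fixture
def noiseless_movie(strong_model, time_grid):
    """Small noiseless rendered movie with ground truth (8 cells, 20 frames)."""
    grid = time_grid[:20]
    condition = fmip.ConditionSpec("egf", (("EGF", 100.0),),
                                   stimulation_time=12.0)
    gt = fmip.make_ground_truth(strong_model, condition, 8, grid, seed=7,
                                image_shape=(300, 300), min_separation=45.0)
    frames = fmip.render_frames(gt, noiseless_camera(), seed=8)
    return gt, frames
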