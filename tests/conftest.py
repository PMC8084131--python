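import numpy as np
import pytest

import pollenvia as pv


@pytest.fixture(scope="session")
def small_training_set():
    """~100 labeled synthetic grains per class (fast, shared)."""
    return pv.synthetic_training_set(n_per_class=100, seed=42)


@pytest.fixture(scope="session")
def trained_model(small_training_set):
    return pv.train_svm(small_training_set, seed=42)


@pytest.fixture()
def disk_mask():
    """Digitized disk of radius 20 centered in a 51x51 grid."""
    yy, xx = np.mgrid[0:51, 0:51]
    return (xx - 25) ** 2 + (yy - 25) ** 2 <= 20 ** 2


@pytest.fixture()
def default_scene():
    return pv.generate_scene(pv.SceneParams(n_viable=20, n_nonviable=5,
                                            touching_fraction=0.0,
                                            noise_sd=3.0, seed=11))
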