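import numpy as np
import pytest
from hypothesis import settings

import ctexture as ct

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def presets():
    classes, sizes, background, levels = ct.load_presets()
    return {
        "classes": classes,
        "sizes": sizes,
        "background": background,
        "levels": levels,
    }


@pytest.fixture(scope="session")
def trained_set():
    """Feature vectors of 20 texture windows per preset class (seeded)."""
    return ct.generate_training_set(20, seed=11)


@pytest.fixture(scope="session")
def trained_norm(trained_set):
    return ct.fit_normalization(trained_set)


def gray(arr, levels=256):
    return ct.GrayImage(np.asarray(arr, dtype=np.int64), levels)


@pytest.fixture
def make_gray():
    return gray
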