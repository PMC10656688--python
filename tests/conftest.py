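import logging

import numpy as np
import pytest

from birads.phantom import (benign_spec, cyst_spec, generate_video,
                            malignant_spec)

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def benign_video():
    return generate_video(benign_spec(seed=0))


@pytest.fixture(scope="session")
def malignant_video():
    return generate_video(malignant_spec(seed=0))


@pytest.fixture(scope="session")
def cyst_video():
    return generate_video(cyst_spec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def speckle_frame(rng, level=0.6, shape=4.0, size=(128, 128)):
    """A lesion-free background frame."""
    return np.clip(level * rng.gamma(shape, 1.0 / shape, size), 0.0, 1.0)
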