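import numpy as np
import pytest

from guidecraft.activity_model import default_grid, train_svm
from guidecraft.screen_io import generate_synthetic_screen, label_by_percentile

#: Small single-point grid for tests that need a model but not a tuned one.
TINY_GRID = {"C": [8.0], "gamma": [2.0**-7]}


@pytest.fixture(scope="session")
def small_screen():
    """300-guide synthetic screen with a strong planted signal."""
    return generate_synthetic_screen(300, seed=11, effect_size=2.0)


@pytest.fixture(scope="session")
def small_labeled(small_screen):
    return label_by_percentile(small_screen)


@pytest.fixture(scope="session")
def small_model(small_labeled):
    """A quickly trained potency model shared across tests."""
    return train_svm(small_labeled, grid=TINY_GRID, seed=1, prefilter=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_guides(rng, n):
    return ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(n)]
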