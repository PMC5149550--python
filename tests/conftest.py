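import numpy as np
import pytest

from fiblab import FigureSpec, generate_study


@pytest.fixture(scope="session")
def figure_spec() -> FigureSpec:
    return FigureSpec()


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete study: 6 children, 20-frame clips, gaze included."""
    return generate_study(n_children=6, seed=7, n_frames=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
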