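import numpy as np
import pytest
from hypothesis import strategies as st

from smwbf.geometry import NormBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng: np.random.Generator, max_size: float = 0.5) -> NormBox:
    """A valid normalized box whose corners stay inside the unit square."""
    w = float(rng.uniform(0.02, max_size))
    h = float(rng.uniform(0.02, max_size))
    cx = float(rng.uniform(w / 2, 1 - w / 2))
    cy = float(rng.uniform(h / 2, 1 - h / 2))
    return NormBox(cx, cy, w, h)


@st.composite
def norm_boxes(draw, min_size: float = 0.01, max_size: float = 0.6):
    """Hypothesis strategy for boxes fully inside the unit square."""
    w = draw(st.floats(min_size, max_size))
    h = draw(st.floats(min_size, max_size))
    cx = draw(st.floats(w / 2, 1 - w / 2))
    cy = draw(st.floats(h / 2, 1 - h / 2))
    return NormBox(cx, cy, w, h)
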