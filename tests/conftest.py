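import numpy as np
import pytest

from plantarfpa.geometry import FootProfile, ImageDims
from plantarfpa.synthetic import generate_sample

PAPER_DIMS = ImageDims(120, 400)


@pytest.fixture(scope="session")
def dims():
    return PAPER_DIMS


@pytest.fixture(scope="session")
def left_out_sample():
    """One noiseless left out-toeing sample at 5 degrees (shared, read-only)."""
    return generate_sample(FootProfile("left", "out"), 5.0, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def random_boxes():
    """Deterministic random valid normalized boxes as (x, y, w, h) rows."""
    rng = np.random.default_rng(2024)
    n = 10_000
    w = rng.uniform(0.0, 1.0, n)
    h = rng.uniform(0.0, 1.0, n)
    x = rng.uniform(w / 2, 1 - w / 2)
    y = rng.uniform(h / 2, 1 - h / 2)
    return np.column_stack([x, y, w, h])
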