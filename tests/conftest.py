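import math

import numpy as np
import pytest
from skimage import draw

from florascreen.morphometrics import BinaryMask


def raster_disc(radius: int, mm_per_px: float = 1.0, pad: int = 10) -> BinaryMask:
    size = 2 * radius + 2 * pad
    grid = np.zeros((size, size), bool)
    rr, cc = draw.disk((size / 2, size / 2), radius)
    grid[rr, cc] = True
    return BinaryMask(grid, mm_per_px=mm_per_px, plant_id="disc", day=0)


def raster_square(side: int, mm_per_px: float = 1.0, pad: int = 10) -> BinaryMask:
    grid = np.zeros((side + 2 * pad, side + 2 * pad), bool)
    grid[pad:pad + side, pad:pad + side] = True
    return BinaryMask(grid, mm_per_px=mm_per_px, plant_id="square", day=0)


def random_blob(rng: np.random.Generator, size: int = 90) -> BinaryMask:
    """Connected union of random ellipses around a central disc."""
    grid = np.zeros((size, size), bool)
    c = size / 2
    rr, cc = draw.disk((c, c), size // 8, shape=grid.shape)
    grid[rr, cc] = True
    for _ in range(rng.integers(2, 6)):
        ang = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(0, size / 5)
        cy, cx = c + dist * math.sin(ang), c + dist * math.cos(ang)
        a, b = rng.uniform(4, size / 5, 2)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=grid.shape,
                              rotation=rng.uniform(0, math.pi))
        grid[rr, cc] = True
    return BinaryMask(grid)


@pytest.fixture
def disc100() -> BinaryMask:
    return raster_disc(100)


@pytest.fixture
def square100() -> BinaryMask:
    return raster_square(100)
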