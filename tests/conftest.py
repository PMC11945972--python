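import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from pupilloc import AppConfig
from pupilloc.refine import Region, connected_components


@pytest.fixture
def cfg() -> AppConfig:
    return AppConfig()


def ellipse_mask(shape, center, a, b, angle=0.0):
    """Rasterize an ellipse (semi-axes a, b; rotation angle) on a grid."""
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xs - center[0]
    dy = ys - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def disc_mask(shape, center, r):
    return ellipse_mask(shape, center, r, r)


def single_region(mask) -> Region:
    regions = connected_components(mask)
    assert len(regions) == 1, f"expected one component, got {len(regions)}"
    return regions[0]


def random_blob_region(rng, n_steps=60) -> Region:
    """Irregular connected blob built from a dilated random walk."""
    grid = np.zeros((80, 80), dtype=bool)
    x, y = 40, 40
    for _ in range(n_steps):
        grid[y, x] = True
        x = int(np.clip(x + rng.integers(-1, 2), 1, 78))
        y = int(np.clip(y + rng.integers(-1, 2), 1, 78))
    grid = ndi.binary_dilation(grid, iterations=1)
    regions = connected_components(grid)
    return max(regions, key=lambda r: r.area)


def candidate_scene_mask(rng):
    """Binary candidate set: pupil ellipse + eyebrow bar + hair-like streaks.

    Streaks are directionally persistent random walks dilated by 1 px and
    kept off the pupil so each candidate is a distinct component.  Returns
    (mask, true pupil center).
    """
    h = w = 200
    mask = np.zeros((h, w), dtype=bool)
    a = rng.uniform(18, 30)
    b = a * rng.uniform(0.85, 1.0)
    angle = rng.uniform(0, math.pi)
    px, py = rng.uniform(80, 120), rng.uniform(90, 140)
    pupil = ellipse_mask((h, w), (px, py), a, b, angle)
    keepout = ndi.binary_dilation(pupil, iterations=3)
    mask |= pupil
    bw = int(rng.uniform(80, 160))
    bh = int(rng.uniform(6, 16))
    bx = int(rng.uniform(0, w - bw))
    by = int(rng.uniform(2, 30))
    mask[by : by + bh, bx : bx + bw] = True
    for _ in range(int(rng.integers(1, 4))):
        sx, sy = rng.uniform(10, 190), rng.uniform(150, 195)
        heading = rng.uniform(0, 2 * math.pi)
        streak = np.zeros((h, w), dtype=bool)
        for _ in range(int(rng.integers(40, 80))):
            heading += rng.normal(0, 0.35)
            sx = min(max(sx + math.cos(heading), 0), w - 1)
            sy = min(max(sy + math.sin(heading), 0), h - 1)
            streak[int(sy), int(sx)] = True
        mask |= ndi.binary_dilation(streak, iterations=1) & ~keepout
    return mask, (px, py)
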