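import math

import numpy as np
import pytest


def gaussian_ridge(angle_rad: float, sigma: float = 1.0, size: int = 64,
                   amplitude: float = 100.0) -> np.ndarray:
    """Straight ridge of Gaussian cross-section through the image center."""
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    nx, ny = -math.sin(angle_rad), math.cos(angle_rad)
    d = (xs - c) * nx + (ys - c) * ny
    return amplitude * np.exp(-d * d / (2 * sigma * sigma))


def quarter_arc_ridge(radius: float = 20.0, sigma: float = 1.0, size: int = 64,
                      amplitude: float = 100.0):
    """Circular-arc ridge plus the two arc endpoints (base, tip)."""
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = size / 2.0, size / 2.0 + 8
    r = np.hypot(xs - cx, ys - cy)
    img = amplitude * np.exp(-(r - radius) ** 2 / (2 * sigma * sigma))
    base = (cx - radius, cy)
    tip = (cx, cy - radius)
    return img, base, tip, (cx, cy)


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
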