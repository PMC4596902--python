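"""Shared raster fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest


def raster_disk(radius: int, pad: int = 6) -> np.ndarray:
    """Boolean raster of a centred disk (pixel-centre inclusion)."""
    n = radius + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx**2 + yy**2) <= radius**2


def raster_ellipse(a: float, b: float, angle: float = 0.0, pad: int = 6) -> np.ndarray:
    """Boolean raster of a centred ellipse with semi-axes a, b, rotated by
    ``angle`` radians."""
    n = int(math.ceil(max(a, b))) + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    u = xx * math.cos(angle) + yy * math.sin(angle)
    v = -xx * math.sin(angle) + yy * math.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def raster_rect(height: int, width: int, pad: int = 6) -> np.ndarray:
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad : pad + height, pad : pad + width] = True
    return m


def brute_force_max_contrast(img: np.ndarray) -> int:
    """Independent exhaustive evaluation of the maximum-average-contrast
    threshold: explicit pair collection, then a per-threshold scan."""
    img = img.astype(np.int64)
    pairs = []
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            if j + 1 < w and img[i, j] != img[i, j + 1]:
                pairs.append(sorted((img[i, j], img[i, j + 1])))
            if i + 1 < h and img[i, j] != img[i + 1, j]:
                pairs.append(sorted((img[i, j], img[i + 1, j])))
    if not pairs:
        raise ValueError("constant image")
    lo, hi = np.array(pairs).T
    best_s, best = -1, -np.inf
    for s in range(255):
        sep = (lo <= s) & (s < hi)
        if not sep.any():
            continue
        contrast = np.minimum(s - lo[sep], hi[sep] - s).mean()
        if contrast > best:
            best, best_s = contrast, s
    return best_s


def brute_force_crofton_2dir(mask: np.ndarray) -> float:
    """Independent 2-direction Crofton estimate by explicit run counting."""
    chords = 0
    for line in list(mask) + list(mask.T):
        prev = False
        for v in line:
            if v and not prev:
                chords += 1
            prev = bool(v)
    return math.pi * chords / 2.0


@pytest.fixture(scope="session")
def disk100() -> np.ndarray:
    return raster_disk(100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130913)
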