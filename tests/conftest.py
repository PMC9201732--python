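"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (nested loops,
direct definitions) and independent of the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np
import pytest

import echodeblur as ed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nerve_phantom():
    return ed.make_phantom(ed.PhantomSpec(seed=0))


@pytest.fixture
def small_phantom():
    return ed.make_phantom(ed.PhantomSpec(size=(64, 64), scene="blobs", seed=3))


# ----------------------------------------------------------------- oracles


def brute_channel(pixels: np.ndarray, patch_size: int, take_max: bool,
                  iterations: int = 1) -> np.ndarray:
    """Nested-loop patch extremum with clipped borders, optionally iterated."""
    r = (patch_size - 1) // 2
    out = pixels
    for _ in range(iterations):
        src = out
        h, w = src.shape
        out = np.empty_like(src)
        for i in range(h):
            for j in range(w):
                win = src[max(0, i - r): i + r + 1, max(0, j - r): j + r + 1]
                out[i, j] = win.max() if take_max else win.min()
    return out


def brute_convolve_interior(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct (true) convolution; valid only on the interior."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    h, w = pixels.shape
    out = np.full((h, w), np.nan)
    for i in range(rh, h - rh):
        for j in range(rw, w - rw):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * pixels[i - (a - rh), j - (b - rw)]
            out[i, j] = acc
    return out


def brute_mse(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    m, n = a.shape
    for i in range(m):
        for j in range(n):
            total += (a[i, j] - b[i, j]) ** 2
    return total / (m * n)


def brute_ssim(a: np.ndarray, b: np.ndarray, max_i: float = 1.0) -> float:
    """Per-window SSIM with explicit Gaussian weights, valid windows only."""
    size, sigma = 11, 1.5
    r = size // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (0.01 * max_i) ** 2
    c2 = (0.03 * max_i) ** 2
    c3 = c2 / 2
    h, wd = a.shape
    vals = []
    for i in range(r, h - r):
        for j in range(r, wd - r):
            pa = a[i - r: i + r + 1, j - r: j + r + 1]
            pb = b[i - r: i + r + 1, j - r: j + r + 1]
            mu1 = (w * pa).sum()
            mu2 = (w * pb).sum()
            s1 = (w * pa * pa).sum() - mu1 ** 2
            s2 = (w * pb * pb).sum() - mu2 ** 2
            s12 = (w * pa * pb).sum() - mu1 * mu2
            s1, s2 = max(s1, 0.0), max(s2, 0.0)
            lum = (2 * mu1 * mu2 + c1) / (mu1 ** 2 + mu2 ** 2 + c1)
            root = np.sqrt(s1 * s2)
            con = (2 * root + c2) / (s1 + s2 + c2)
            st = (s12 + c3) / (root + c3)
            vals.append(lum * con * st)
    return float(np.mean(vals))


def kernel_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation maximized over alignment."""
    from scipy.signal import correlate2d

    c = correlate2d(a, b, mode="full")
    return float(c.max() / (np.linalg.norm(a) * np.linalg.norm(b)))
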