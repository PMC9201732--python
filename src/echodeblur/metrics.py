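"""Image-quality evaluation: MSE, PSNR with quality bands, and SSIM.

PSNR is ``10·log10(MAX_I² / MSE)`` in dB with ``MAX_I = 1`` on the package's
internal intensity scale; identical images yield an infinite PSNR, returned
as the ``float('inf')`` sentinel rather than raising. Quality bands follow
the usual reading for 8-bit-scale imagery: above 40 dB excellent, 30-40 dB
good, 20-30 dB poor, below 20 dB unacceptable; the 30 and 20 dB boundaries
are assigned to the better band, while exactly 40 dB stays "good" (excellent
requires strictly more than 40).

SSIM is the windowed product l^alpha · c^beta · s^gamma of luminance,
contrast, and structure comparisons. The parameterization is the canonical
one: 11x11 Gaussian window (sigma = 1.5), stabilizers C1 = (0.01·L)²,
C2 = (0.03·L)², C3 = C2/2, exponents all 1, under which the product reduces
to the familiar two-term form. SSIM is often described as lying in [0, 1];
mathematically the structure term can go negative, and negative values are
reported as computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .image_model import ParameterError, UltrasoundImage

__all__ = ["QualityReport", "mse", "psnr", "quality_grade", "ssim", "evaluate_pair"]

_SSIM_WINDOW = 11
_SSIM_SIGMA = 1.5


@dataclass(frozen=True)
class QualityReport:
    mse: float
    psnr: float  # dB; math.inf when mse == 0
    ssim: float
    grade: str


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, UltrasoundImage) else np.asarray(img, float)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a, b) -> float:
    """Mean squared difference over all pixels."""
    pa, pb = _pixels(a), _pixels(b)
    _check_shapes(pa, pb)
    return float(np.mean((pa - pb) ** 2))


def psnr(a, b, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    if max_i <= 0:
        raise ParameterError("max_i must be > 0")
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_i**2 / err)


def quality_grade(psnr_db: float) -> str:
    """Map a PSNR value onto the four-band quality scale."""
    if psnr_db > 40.0:
        return "excellent"
    if psnr_db >= 30.0:
        return "good"
    if psnr_db >= 20.0:
        return "poor"
    return "unacceptable"


def _gaussian_window(size: int = _SSIM_WINDOW, sigma: float = _SSIM_SIGMA) -> np.ndarray:
    r = (size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(a, b, exponents: tuple[float, float, float] = (1.0, 1.0, 1.0),
         max_i: float = 1.0) -> float:
    """Mean structural similarity over sliding Gaussian windows.

    Windows are fully interior ('valid' convolution): images must be at least
    the window size (11) per axis.
    """
    pa, pb = _pixels(a), _pixels(b)
    _check_shapes(pa, pb)
    if min(pa.shape) < _SSIM_WINDOW:
        raise ParameterError(
            f"image {pa.shape} smaller than the {_SSIM_WINDOW}x{_SSIM_WINDOW} SSIM window"
        )
    alpha, beta, gamma = exponents
    w = _gaussian_window()
    conv = lambda x: fftconvolve(x, w, mode="valid")
    mu1, mu2 = conv(pa), conv(pb)
    s1 = np.clip(conv(pa * pa) - mu1**2, 0.0, None)
    s2 = np.clip(conv(pb * pb) - mu2**2, 0.0, None)
    s12 = conv(pa * pb) - mu1 * mu2
    c1 = (0.01 * max_i) ** 2
    c2 = (0.03 * max_i) ** 2
    c3 = c2 / 2.0
    lum = (2.0 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
    root = np.sqrt(s1 * s2)
    con = (2.0 * root + c2) / (s1 + s2 + c2)
    struct = (s12 + c3) / (root + c3)
    # signed powers keep non-integer exponents well defined when s < 0
    spow = lambda x, p: np.sign(x) * np.abs(x) ** p
    return float(np.mean(spow(lum, alpha) * spow(con, beta) * spow(struct, gamma)))


def evaluate_pair(reference, test, max_i: float = 1.0) -> QualityReport:
    """Full quality report of ``test`` against ``reference``."""
    err = mse(reference, test)
    p = psnr(reference, test, max_i=max_i)
    s = ssim(reference, test, max_i=max_i)
    return QualityReport(mse=err, psnr=p, ssim=s, grade=quality_grade(p))
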