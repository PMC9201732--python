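"""Patch-extremum operators: dark/bright channels and their secondary sparse variants.

The dark channel of a grayscale image is the per-pixel minimum over a square
window phi(u) centered at u; the bright channel is the per-pixel maximum.
Applying the same operator a second time gives the *secondary sparse*
channels, which for square windows equal a single pass with twice the window
radius. Sharp ultrasound scenes contain genuinely dark pixels (vessel lumens)
and genuinely bright pixels (fascia); blurring averages these extremes away,
which is what makes channel sparsity a useful deblurring prior.

Windows are clipped at the image boundary: no padding value ever participates
in an extremum. Each operator also records, per output pixel, one window
coordinate attaining the extremum (the patch center when it ties, else the
first occurrence in row-major order), which lets the solver freeze the
nonlinear min/max into a linear pixel-selection operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numpy.lib.stride_tricks import sliding_window_view

from .image_model import ParameterError, UltrasoundImage

__all__ = [
    "ChannelResult",
    "dark_channel",
    "bright_channel",
    "secondary_sparse_dark",
    "secondary_sparse_bright",
    "selection_operator",
    "sparsity_count",
]

#: intensities above this count as "non-zero" when reporting channel sparsity
SPARSITY_TOL = 1e-3


@dataclass(frozen=True)
class ChannelResult:
    """Channel values plus the per-pixel coordinates attaining each extremum."""

    values: np.ndarray
    arg_rows: np.ndarray
    arg_cols: np.ndarray
    patch_size: int
    kind: str  # "dark" or "bright"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _axis_extremum(arr: np.ndarray, radius: int, axis: int, take_max: bool):
    """Sliding window extremum with clipped borders along one axis.

    Returns (values, absolute index of the extremum along ``axis``).
    Out-of-bounds window slots are padded with +/-inf so they never win;
    np.argmin/argmax then yields the first in-bounds occurrence.
    """
    if radius == 0:
        idx = np.arange(arr.shape[axis])
        idx = np.expand_dims(idx, axis=1 - axis)
        return arr.copy(), np.broadcast_to(idx, arr.shape).copy()
    fill = -np.inf if take_max else np.inf
    pad = [(0, 0), (0, 0)]
    pad[axis] = (radius, radius)
    padded = np.pad(arr, pad, mode="constant", constant_values=fill)
    win = sliding_window_view(padded, 2 * radius + 1, axis=axis)
    if take_max:
        vals = win.max(axis=-1)
        offs = win.argmax(axis=-1)
    else:
        vals = win.min(axis=-1)
        offs = win.argmin(axis=-1)
    # window position i covers absolute indices [i-radius, i+radius]
    base = np.arange(arr.shape[axis]) - radius
    base = np.expand_dims(base, axis=1 - axis)
    return vals, offs + base


def window_extremum(pixels: np.ndarray, radius: int, take_max: bool,
                    tie_tol: float = 0.0):
    """Clipped-window extremum over (2*radius+1)^2 patches with arg maps.

    Separable: a horizontal pass then a vertical pass. Ties resolve to the
    patch center when the center attains the extremum (within ``tie_tol``),
    otherwise to the first occurrence in row-major order. The solver passes a
    small ``tie_tol`` so that float ripple on flat regions does not
    concentrate the selection onto arbitrary pixels.
    """
    vals_h, cols_h = _axis_extremum(pixels, radius, axis=1, take_max=take_max)
    vals, rows = _axis_extremum(vals_h, radius, axis=0, take_max=take_max)
    cols = np.take_along_axis(cols_h, rows, axis=0)
    h, w = pixels.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    center_ties = np.abs(pixels - vals) <= tie_tol
    rows = np.where(center_ties, rr, rows)
    cols = np.where(center_ties, cc, cols)
    return vals, rows, cols


def _channel(img: UltrasoundImage, patch_size: int, take_max: bool, secondary: bool):
    if patch_size < 1 or patch_size % 2 == 0:
        raise ParameterError(f"patch_size must be odd and >= 1, got {patch_size}")
    radius = (patch_size - 1) // 2
    if secondary:
        radius *= 2  # iterated clipped min/max == one pass at twice the radius
    vals, rows, cols = window_extremum(img.pixels, radius, take_max)
    return ChannelResult(
        values=vals,
        arg_rows=rows,
        arg_cols=cols,
        patch_size=patch_size,
        kind="bright" if take_max else "dark",
    )


def dark_channel(img: UltrasoundImage, patch_size: int) -> ChannelResult:
    """Per-pixel minimum over the clipped window phi(u)."""
    return _channel(img, patch_size, take_max=False, secondary=False)


def bright_channel(img: UltrasoundImage, patch_size: int) -> ChannelResult:
    """Per-pixel maximum over the clipped window phi(u)."""
    return _channel(img, patch_size, take_max=True, secondary=False)


def secondary_sparse_dark(img: UltrasoundImage, patch_size: int) -> ChannelResult:
    """Dark channel of the dark channel (min filter at twice the radius)."""
    return _channel(img, patch_size, take_max=False, secondary=True)


def secondary_sparse_bright(img: UltrasoundImage, patch_size: int) -> ChannelResult:
    """Bright channel of the bright channel (max filter at twice the radius)."""
    return _channel(img, patch_size, take_max=True, secondary=True)


def selection_operator(result: ChannelResult, shape: tuple[int, int]) -> sp.csr_matrix:
    """Linearize a channel at its recorded extrema.

    Returns the sparse (H*W, H*W) matrix with exactly one unit entry per row,
    mapping a flattened image to its flattened channel values: applying it to
    the image the result was computed from reproduces ``result.values``.
    """
    if tuple(result.values.shape) != tuple(shape):
        raise ParameterError(
            f"channel shape {result.values.shape} does not match image shape {shape}"
        )
    h, w = shape
    n = h * w
    cols = (result.arg_rows * w + result.arg_cols).ravel()
    if cols.min() < 0 or cols.max() >= n:
        raise ParameterError("extremum coordinates fall outside the image")
    rows = np.arange(n)
    data = np.ones(n)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def sparsity_count(values: np.ndarray, kind: str, tol: float = SPARSITY_TOL) -> int:
    """Thresholded L0 surrogate of a channel map.

    For a dark channel, counts entries above ``tol``; for a bright channel,
    counts entries whose complement 1-v exceeds ``tol``.
    """
    if kind == "dark":
        return int(np.count_nonzero(values > tol))
    if kind == "bright":
        return int(np.count_nonzero(values < 1.0 - tol))
    raise ParameterError(f"kind must be 'dark' or 'bright', got {kind!r}")
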