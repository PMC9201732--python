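"""Core containers for ultrasound deblurring: images, blur kernels, solver config.

Intensities live on a single internal scale, real values in [0, 1]; the
full-scale intensity ``MAX_I`` used by PSNR is therefore 1.0 by default.
Raster I/O (8/16-bit PNG and TIFF) maps the integer bit-depth maximum onto
1.0 and back. The coordinate convention is row-major, 0-based ``(row, col)``;
a kernel of side ``k`` has its center at ``((k-1)/2, (k-1)/2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

__all__ = [
    "EchoDeblurError",
    "FormatError",
    "ParameterError",
    "SolverError",
    "DataError",
    "UltrasoundImage",
    "BlurKernel",
    "DeblurConfig",
    "read_image",
    "write_image",
]

_LOG = logging.getLogger(__name__)

#: luma weights used for RGB -> grayscale reduction (ITU-R BT.709, as used by
#: skimage.color.rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class EchoDeblurError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EchoDeblurError, ValueError):
    """Unsupported raster format or bit depth."""


class ParameterError(EchoDeblurError, ValueError):
    """Invalid parameter or incompatible shapes."""


class SolverError(EchoDeblurError, RuntimeError):
    """The optimization produced a degenerate or non-finite state."""


class DataError(EchoDeblurError, ValueError):
    """Inconsistent clinical summary data."""


@dataclass(frozen=True)
class UltrasoundImage:
    """A 2-D grayscale intensity field, normalized to [0, 1].

    Holds either a latent (sharp) image or a blurred observation. All
    intensities are finite float64 values in [0, 1]; construction validates
    this so every downstream operation can rely on it.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ParameterError(f"image must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ParameterError("image must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("image contains non-finite intensities")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ParameterError(
                f"intensities must lie in [0, 1], got range "
                f"[{arr.min():.6g}, {arr.max():.6g}]"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, clip: bool = False) -> "UltrasoundImage":
        """Wrap an array, optionally clipping to [0, 1] first."""
        arr = np.asarray(arr, dtype=np.float64)
        if clip:
            arr = np.clip(arr, 0.0, 1.0)
        return cls(arr)

    def require_min_size(self, min_side: int = 8) -> None:
        """Solver entry points require images of at least ``min_side`` per axis."""
        if self.height < min_side or self.width < min_side:
            raise ParameterError(
                f"image {self.shape} smaller than required {min_side}x{min_side}"
            )


@dataclass(frozen=True)
class BlurKernel:
    """A small non-negative point-spread function with unit mass.

    The kernel is square with odd side length so it has an unambiguous center
    pixel; weights sum to 1 within 1e-8.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError(f"kernel must be square 2-D, got shape {w.shape}")
        if w.shape[0] % 2 == 0:
            raise ParameterError(f"kernel side must be odd, got {w.shape[0]}")
        if not np.all(np.isfinite(w)):
            raise ParameterError("kernel contains non-finite weights")
        if w.min() < 0.0:
            raise ParameterError(f"kernel weights must be >= 0, min {w.min():.3g}")
        total = w.sum()
        if abs(total - 1.0) > 1e-8:
            raise ParameterError(f"kernel mass must be 1 within 1e-8, got {total!r}")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def support(self) -> int:
        return self.weights.shape[0]

    @property
    def center(self) -> tuple[int, int]:
        c = (self.support - 1) // 2
        return (c, c)

    @classmethod
    def from_array(cls, arr: np.ndarray, normalize: bool = False) -> "BlurKernel":
        arr = np.asarray(arr, dtype=np.float64)
        if normalize:
            arr = np.clip(arr, 0.0, None)
            total = arr.sum()
            if total <= 0:
                raise SolverError("cannot normalize an all-zero kernel")
            arr = arr / total
        return cls(arr)

    @classmethod
    def delta(cls, size: int = 3) -> "BlurKernel":
        """Identity kernel: unit weight at the center."""
        _check_odd(size, "kernel size")
        w = np.zeros((size, size))
        w[(size - 1) // 2, (size - 1) // 2] = 1.0
        return cls(w)

    @classmethod
    def gaussian(cls, size: int, sigma: float) -> "BlurKernel":
        """Isotropic Gaussian PSF truncated to ``size`` x ``size``."""
        _check_odd(size, "kernel size")
        if sigma <= 0:
            raise ParameterError("sigma must be > 0")
        r = (size - 1) // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        g = np.exp(-(x**2) / (2.0 * sigma**2))
        w = np.outer(g, g)
        return cls(w / w.sum())

    @classmethod
    def motion(cls, size: int, length: float, angle_deg: float) -> "BlurKernel":
        """Linear motion PSF: an anti-aliased line segment through the center."""
        _check_odd(size, "kernel size")
        if length < 1:
            raise ParameterError("motion length must be >= 1")
        if length > size * math.sqrt(2.0):
            raise ParameterError("motion length exceeds kernel support")
        c = (size - 1) / 2.0
        theta = math.radians(angle_deg)
        dx, dy = math.cos(theta), -math.sin(theta)
        # supersample the segment and bin into the kernel grid
        n = max(64, int(32 * length))
        t = np.linspace(-(length - 1) / 2.0, (length - 1) / 2.0, n)
        rows = np.clip(np.round(c + t * dy).astype(int), 0, size - 1)
        cols = np.clip(np.round(c + t * dx).astype(int), 0, size - 1)
        w = np.zeros((size, size))
        np.add.at(w, (rows, cols), 1.0)
        return cls(w / w.sum())

    def is_delta(self, tol: float = 0.0) -> bool:
        """True if the kernel is the identity within ``tol`` off-center mass."""
        w = self.weights
        off = w.sum() - w[self.center]
        return off <= tol


def _check_odd(value: int, name: str) -> None:
    if not isinstance(value, (int, np.integer)) or value < 1 or value % 2 == 0:
        raise ParameterError(f"{name} must be an odd integer >= 1, got {value!r}")


@dataclass(frozen=True)
class DeblurConfig:
    """All solver hyperparameters.

    Weights follow the joint objective
    ``||M ⊗ h − Z||² + phi·||h||² + vartheta·[theta·L0(S(A_M)) +
    zeta·L0(1 − S(Z_M))] + grad_weight·L0(∇M)``:

    phi
        ridge weight on the kernel (default 2).
    vartheta
        global weight on the extreme-channel prior block (default 1).
    theta, zeta
        dark-channel and bright-channel-complement sparsity weights
        (default 4e-3 each).
    grad_weight
        gradient-L0 weight used both inside kernel estimation and in the
        final non-blind restoration (default 4e-3).
    patch_size
        side of the extremum window phi(u) (odd, default 15); the secondary
        sparse channels use twice this radius.
    kernel_size
        odd side of the estimated kernel (default 15).
    pyramid_levels
        number of coarse-to-fine levels; None selects the largest number of
        levels keeping the coarsest kernel at least 5 px.
    scale_factor
        per-level downscale in (0, 1), default 0.75.
    outer_iters, inner_iters
        alternating image/kernel rounds per level, and half-quadratic
        splitting rounds per image update (penalty doubles each round,
        starting at 2·theta).
    kernel_threshold
        after each kernel solve, entries below this fraction of the maximum
        are zeroed before renormalization (default 0.05).
    seed
        governs any stochastic element; the solver itself is deterministic.
    """

    phi: float = 2.0
    vartheta: float = 1.0
    theta: float = 4e-3
    zeta: float = 4e-3
    grad_weight: float = 4e-3
    patch_size: int = 15
    kernel_size: int = 15
    pyramid_levels: int | None = None
    scale_factor: float = 0.75
    outer_iters: int = 5
    inner_iters: int = 4
    kernel_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phi", "vartheta", "theta", "zeta", "grad_weight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite weight >= 0, got {v}")
        for name in ("patch_size", "kernel_size"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ParameterError(f"{name} must be odd and >= 3, got {v}")
        if not (0.0 < self.scale_factor < 1.0):
            raise ParameterError("scale_factor must lie in (0, 1)")
        if self.pyramid_levels is not None and self.pyramid_levels < 1:
            raise ParameterError("pyramid_levels must be >= 1")
        for name in ("outer_iters", "inner_iters"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not (0.0 <= self.kernel_threshold < 1.0):
            raise ParameterError("kernel_threshold must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_updates(self, **kwargs) -> "DeblurConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DeblurConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def read_image(path: str | Path) -> UltrasoundImage:
    """Read an 8- or 16-bit PNG/TIFF as a normalized grayscale image.

    RGB(A) inputs are reduced to grayscale by standard luma weighting (a
    warning is logged); intensities are scaled to [0, 1] by the bit-depth
    maximum (255 or 65535).
    """
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    else:
        raise FormatError(
            f"unsupported bit depth {arr.dtype} in {path}; expected uint8 or uint16"
        )
    data = arr.astype(np.float64) / maxval
    if data.ndim == 3:
        if data.shape[2] == 4:  # drop alpha
            data = data[:, :, :3]
        if data.shape[2] != 3:
            raise FormatError(f"unsupported channel count {data.shape[2]} in {path}")
        _LOG.warning("RGB input %s converted to grayscale by luma weighting", path)
        data = data @ _LUMA
    elif data.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return UltrasoundImage.from_array(np.clip(data, 0.0, 1.0))


def write_image(img: UltrasoundImage, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a normalized image as an 8- or 16-bit single-channel PNG/TIFF.

    Round-tripping through :func:`read_image` reproduces the image within one
    quantization step of the chosen bit depth.
    """
    if bit_depth == 8:
        dtype, maxval = np.uint8, 255.0
    elif bit_depth == 16:
        dtype, maxval = np.uint16, 65535.0
    else:
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    quantized = np.round(img.pixels * maxval).astype(dtype)
    iio.imwrite(path, quantized)
    return path
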