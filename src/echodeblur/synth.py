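"""Synthetic ultrasound phantoms and their degradation model.

The generator supplies ground-truthed fixtures for the solver and metric
stack. The ``nerve_region`` scene sketches what a femoral nerve-block
operator sees: a mid-gray speckle-textured background, a hypoechoic (dark)
vessel lumen, an echogenic nerve cross-section with a honeycomb fascicle
pattern, and bright fascia bands. The scene deliberately contains genuinely
dark (< 0.05) and genuinely bright (> 0.95) pixels so the extreme-channel
priors have something to grip.

Degradation follows observation = clip(speckle(truth ⊗ kernel)): blur models
probe/tissue motion during acquisition, then multiplicative speckle is the
terminal observation noise. ``speckle_snr_db`` is referenced to full-scale
intensity (MAX_I = 1), i.e. it is the expected PSNR of the speckled image
against its clean input. Everything is seeded and bit-reproducible: a
DegradedPair can be regenerated exactly from its spec (or a manifest row).

This is a geometric phantom, not a wave-propagation simulation: there is no
point-scatterer physics, attenuation, or scan-conversion geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import BlurKernel, ParameterError, UltrasoundImage, write_image

__all__ = [
    "PhantomSpec",
    "DegradedPair",
    "make_phantom",
    "make_kernel",
    "apply_blur",
    "add_speckle",
    "generate_pair",
    "default_suite",
    "make_benchmark_suite",
]

_SCENES = ("nerve_region", "bars", "blobs")
_SPECKLE_MODELS = ("none", "rayleigh", "gamma")
_KERNEL_TYPES = ("delta", "gaussian", "motion")

#: variance of a unit-mean Rayleigh variable (fixed by the law's shape)
_RAYLEIGH_UNIT_VAR = 4.0 / math.pi - 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scene and its degradation."""

    size: tuple[int, int] = (128, 128)
    scene: str = "nerve_region"
    speckle_model: str = "rayleigh"
    speckle_snr_db: float = 20.0
    kernel_type: str = "motion"
    kernel_size: int = 9
    kernel_sigma: float = 1.5  # gaussian kernels
    motion_length: float | None = None  # None -> drawn in [5, 9] from seed
    motion_angle_deg: float | None = None  # None -> drawn uniformly from seed
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ParameterError(f"phantom size must be >= 32x32, got {self.size}")
        if self.scene not in _SCENES:
            raise ParameterError(f"unknown scene {self.scene!r}; choose from {_SCENES}")
        if self.speckle_model not in _SPECKLE_MODELS:
            raise ParameterError(
                f"unknown speckle model {self.speckle_model!r}; choose from {_SPECKLE_MODELS}"
            )
        if self.kernel_type not in _KERNEL_TYPES:
            raise ParameterError(
                f"unknown kernel type {self.kernel_type!r}; choose from {_KERNEL_TYPES}"
            )
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ParameterError("kernel_size must be odd and >= 1")
        if self.kernel_size >= min(self.size) / 4:
            raise ParameterError("kernel_size must be smaller than min(size)/4")
        if not np.isfinite(self.speckle_snr_db):
            raise ParameterError("speckle_snr_db must be finite")


@dataclass(frozen=True)
class DegradedPair:
    """A ground-truthed (truth, observed, kernel) triple plus its spec."""

    truth: UltrasoundImage
    observed: UltrasoundImage
    kernel: BlurKernel
    spec: PhantomSpec
    # realized motion parameters (equal to the spec's when given there)
    motion_length: float | None = None
    motion_angle_deg: float | None = None


def _rng(seed, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams per stage of the pipeline
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _disk(h: int, w: int, cr: float, cc: float, radius: float, soft: float = 1.5):
    rr, cc_ = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(rr - cr, cc_ - cc)
    return np.clip((radius - d) / soft + 0.5, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> UltrasoundImage:
    """Deterministic scene for the spec's seed."""
    h, w = spec.size
    rng = _rng(spec.seed, 0)
    if spec.scene == "bars":
        # piecewise-constant vertical bars with known edge positions
        levels = [0.1, 0.5, 0.9, 0.3, 0.7]
        img = np.empty((h, w))
        bar = max(4, w // 8)
        for j in range(0, w, bar):
            img[:, j : j + bar] = levels[(j // bar) % len(levels)]
        return UltrasoundImage(img)
    if spec.scene == "blobs":
        img = np.full((h, w), 0.5)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for _ in range(8):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            sig = rng.uniform(0.04, 0.12) * min(h, w)
            amp = rng.uniform(-0.45, 0.45)
            img += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sig**2))
        return UltrasoundImage(np.clip(img, 0.0, 1.0))

    # nerve_region
    base = 0.45 + 0.08 * ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 10)
    img = np.clip(base, 0.3, 0.65)

    # bright fascia bands: gently curved, near-saturated
    x = np.arange(w)
    rows = np.arange(h)[:, None]
    for frac, amp_frac in ((0.18, 0.015), (0.32, 0.02)):
        y0 = frac * h + rng.uniform(-0.02, 0.02) * h
        amp = amp_frac * h
        phase = rng.uniform(0, 2 * math.pi)
        band_center = y0 + amp * np.sin(2 * math.pi * x / w + phase)
        thickness = rng.uniform(1.5, 2.5)
        mask = np.clip(thickness - np.abs(rows - band_center[None, :]), 0.0, 1.0)
        img = img * (1 - mask) + mask * rng.uniform(0.97, 1.0)

    # hypoechoic vessel lumen (dark circle, soft wall)
    vr = rng.uniform(0.09, 0.12) * min(h, w)
    vcy = rng.uniform(0.6, 0.75) * h
    vcx = rng.uniform(0.2, 0.35) * w
    lumen = _disk(h, w, vcy, vcx, vr)
    img = img * (1 - lumen) + lumen * rng.uniform(0.0, 0.02)

    # echogenic nerve cross-section: bright rim, honeycomb fascicles
    nr = rng.uniform(0.13, 0.16) * min(h, w)
    ncy = rng.uniform(0.5, 0.65) * h
    ncx = rng.uniform(0.6, 0.75) * w
    rim = _disk(h, w, ncy, ncx, nr)
    inner = _disk(h, w, ncy, ncx, nr * 0.82)
    img = img * (1 - rim) + rim * 0.92  # hyperechoic epineurium
    img = img * (1 - inner) + inner * 0.72  # interior
    n_fasc = 7
    for i in range(n_fasc):
        ang = 2 * math.pi * i / n_fasc + rng.uniform(-0.2, 0.2)
        rad = nr * (0.45 if i else 0.0)
        fy, fx = ncy + rad * math.sin(ang), ncx + rad * math.cos(ang)
        fasc = _disk(h, w, fy, fx, nr * rng.uniform(0.16, 0.22))
        img = img * (1 - fasc) + fasc * rng.uniform(0.25, 0.35)

    return UltrasoundImage(np.clip(img, 0.0, 1.0))


def make_kernel(spec: PhantomSpec) -> tuple[BlurKernel, float | None, float | None]:
    """Build the spec's kernel; returns realized (kernel, length, angle)."""
    if spec.kernel_type == "delta":
        return BlurKernel.delta(spec.kernel_size), None, None
    if spec.kernel_type == "gaussian":
        return BlurKernel.gaussian(spec.kernel_size, spec.kernel_sigma), None, None
    rng = _rng(spec.seed, 1)
    length = spec.motion_length
    if length is None:
        length = float(rng.uniform(5.0, 9.0))
    angle = spec.motion_angle_deg
    if angle is None:
        angle = float(rng.uniform(0.0, 180.0))
    if length > spec.kernel_size * math.sqrt(2.0):
        raise ParameterError("motion length exceeds kernel support")
    return BlurKernel.motion(spec.kernel_size, length, angle), length, angle


def apply_blur(img: UltrasoundImage, kernel: BlurKernel) -> UltrasoundImage:
    """Direct 2-D convolution with border-clipped, renormalized kernel mass.

    Near the boundary only the in-bounds part of the kernel contributes and
    its mass is renormalized to 1, so constants stay constant and a delta
    kernel is exactly the identity.
    """
    if kernel.support > min(img.shape):
        raise ParameterError(
            f"kernel {kernel.support} larger than image {img.shape}"
        )
    num = ndimage.convolve(img.pixels, kernel.weights, mode="constant", cval=0.0)
    den = ndimage.convolve(
        np.ones(img.shape), kernel.weights, mode="constant", cval=0.0
    )
    # den can reach 0 in a corner when the kernel mass sits far off-center
    return UltrasoundImage.from_array(num / np.maximum(den, 1e-12), clip=True)


def add_speckle(img: UltrasoundImage, model: str, snr_db: float, seed) -> UltrasoundImage:
    """Multiplicative unit-mean speckle scaled to a full-scale-referenced SNR.

    The multiplier's variance is chosen so the expected noise power equals
    ``MAX_I² · 10^(-snr_db/10)``, i.e. the speckled image has expected PSNR
    ``snr_db`` against its input (realized within ~0.5 dB on images of at
    least 64x64, before the effect of clipping at the intensity extremes).
    ``rayleigh`` uses a scaled, centered Rayleigh fluctuation (a unit-mean
    Rayleigh has fixed variance 4/π−1, so the target is hit by scaling);
    ``gamma`` uses a unit-mean Gamma(k, 1/k) multiplier with k = 1/variance.
    """
    if model == "none":
        return img
    if model not in _SPECKLE_MODELS:
        raise ParameterError(f"unknown speckle model {model!r}")
    if not np.isfinite(snr_db):
        raise ParameterError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    power = np.mean(img.pixels**2)
    if power <= 0:
        return img
    var_eta = 10.0 ** (-snr_db / 10.0) / power
    if model == "rayleigh":
        raw = rng.rayleigh(scale=1.0, size=img.shape)
        unit = raw / math.sqrt(math.pi / 2.0)  # unit mean
        a = math.sqrt(var_eta / _RAYLEIGH_UNIT_VAR)
        eta = 1.0 + a * (unit - 1.0)
    else:  # gamma
        k = 1.0 / var_eta
        eta = rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
    eta = np.clip(eta, 0.0, None)
    return UltrasoundImage.from_array(img.pixels * eta, clip=True)


def generate_pair(spec: PhantomSpec) -> DegradedPair:
    """Build a ground-truthed degraded pair; bit-reproducible from the spec."""
    truth = make_phantom(spec)
    kernel, length, angle = make_kernel(spec)
    blurred = apply_blur(truth, kernel)
    observed = add_speckle(
        blurred, spec.speckle_model, spec.speckle_snr_db,
        np.random.SeedSequence([int(spec.seed), 2]),
    )
    return DegradedPair(
        truth=truth, observed=observed, kernel=kernel, spec=spec,
        motion_length=length, motion_angle_deg=angle,
    )


def default_suite(n: int = 20, base_seed: int = 0) -> list[DegradedPair]:
    """The standard phantom suite: 128x128 nerve scenes, motion blur of
    length 5-9 at random angles, Rayleigh speckle at 20 dB SNR."""
    return [generate_pair(PhantomSpec(seed=base_seed + i)) for i in range(n)]


def make_benchmark_suite(
    out_dir: str | Path,
    n: int,
    base_seed: int,
    scene: str = "nerve_region",
    snr_db: float = 20.0,
    size: tuple[int, int] = (128, 128),
) -> pd.DataFrame:
    """Write n degraded pairs plus a CSV manifest; any manifest row suffices
    to regenerate its pair bit-identically."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        spec = PhantomSpec(
            size=size, scene=scene, speckle_snr_db=snr_db, seed=base_seed + i
        )
        pair = generate_pair(spec)
        stem = f"pair{i:03d}"
        write_image(pair.truth, out_dir / f"{stem}_truth.png", bit_depth=16)
        write_image(pair.observed, out_dir / f"{stem}_observed.png", bit_depth=16)
        np.savetxt(out_dir / f"{stem}_kernel.txt", pair.kernel.weights)
        from .metrics import psnr

        rows.append(
            {
                "pair": stem,
                "seed": spec.seed,
                "scene": spec.scene,
                "height": size[0],
                "width": size[1],
                "speckle_model": spec.speckle_model,
                "speckle_snr_db": spec.speckle_snr_db,
                "kernel_type": spec.kernel_type,
                "kernel_size": spec.kernel_size,
                "motion_length": pair.motion_length,
                "motion_angle_deg": pair.motion_angle_deg,
                "psnr_observed_db": psnr(pair.truth, pair.observed),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def pair_from_manifest_row(row) -> DegradedPair:
    """Regenerate a pair from one manifest row (bit-identical to the original)."""
    spec = PhantomSpec(
        size=(int(row["height"]), int(row["width"])),
        scene=str(row["scene"]),
        speckle_model=str(row["speckle_model"]),
        speckle_snr_db=float(row["speckle_snr_db"]),
        kernel_type=str(row["kernel_type"]),
        kernel_size=int(row["kernel_size"]),
        seed=int(row["seed"]),
    )
    return generate_pair(spec)
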