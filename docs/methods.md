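# Methods

## The restoration model

An ultrasound observation `Z` is modeled as a sharp latent image `M`
convolved with an unknown point-spread function `h` and corrupted by
multiplicative speckle:

    Z = clip( speckle( M ⊗ h ) ),     M ∈ [0,1]^{H×W},  h ≥ 0,  Σh = 1.

Blind deblurring estimates `(M, h)` jointly from a single `Z` by minimizing

    ‖M ⊗ h − Z‖₂²  +  φ‖h‖₂²
      +  ϑ·[ θ·L0(S(A_M)) + ζ·L0(1 − S(Z_M)) ]  +  λ_g·L0(∇M),

where `A_M` and `Z_M` are the dark and bright channels — per-pixel minimum
and maximum over a square window φ(u) — and `S(·)` applies the same operator
a second time (the *secondary sparse* channels; for square windows this
equals one pass at twice the radius). The premise: sharp nerve-region
ultrasound contains genuinely dark pixels (vessel lumens, shadowing) and
genuinely bright pixels (fascia, epineurium). Blur averages those extremes
toward gray, so the counts of non-dark dark-channel pixels and non-bright
bright-channel pixels both rise under blur; penalizing them favors sharp
latents. The gradient-L0 term is an addition to the channel priors: it is
what stabilizes kernel estimation and regularizes the final non-blind
restoration, and we state it openly as part of this implementation's
objective. `L0` is realized as a thresholded count (entries above 1e−3, or
below 1−1e−3 for the bright complement) for reporting, and as hard-threshold
proximal steps inside the solver.

## Optimization

Alternating minimization over a coarse-to-fine pyramid
(`scale_factor = 0.75`; levels chosen so the coarsest kernel is ≥ 5 px).

**Image step** (`estimate_latent`) — half-quadratic splitting with auxiliary
variables for the dark-channel map, the bright-complement map, and the
gradient field. Each inner round: (1) hard-threshold the auxiliaries (the
exact L0 proximal map); (2) freeze the min/max operators at their current
argmin/argmax so each channel becomes a linear pixel selection; (3) solve
the remaining quadratic by preconditioned conjugate gradients. The selection
terms are diagonal in image space and the convolution/gradient terms are
diagonal in Fourier space; no single basis diagonalizes the system, hence
CG with a Fourier preconditioner (`|K̂|² + β_g·|Ĝ|² + 2β`). The splitting
penalty starts at `2θ` and doubles each of the `inner_iters = 4` rounds.
Argmin/argmax ties resolve to the window center when the center attains the
extremum (within 1e−12 in the solver), else to the first occurrence in
row-major order; center preference makes constant images exact fixed points
of the frozen selections, so flat inputs stay exactly flat.

**Kernel step** (`estimate_kernel`) — minimizes
`‖∇M ⊗ h − ∇Z‖₂² + φ‖h‖₂²` exactly over the kernel support via dense normal
equations: the Gram matrix is the circular autocorrelation of the latent
gradients evaluated at offset lags (computed with FFTs), the right side
their cross-correlation with the observed gradients. Four iteratively
reweighted rounds (`w_i = φ/(|h_i|+1e−4)`) turn the ridge into an L1-like
penalty so thin motion kernels stay thin — plain Fourier division thickens
a one-pixel line into two and caps its correlation with the truth near 0.7.
The solution is projected: negatives zeroed, entries below
`kernel_threshold·max(h)` zeroed, largest 8-connected component kept,
center-of-mass aligned to the kernel center (integer roll plus sub-pixel
linear shift — a one-pixel drift costs several dB in the restoration), and
renormalized to unit mass.

Two pre-processing details protect the kernel step. The latent fed into it
is *conditionally despiked*: pixels differing from their 3×3 median by more
than 0.03 (on the [0,1] scale) are replaced by that median. The channel prior pulls selected
window extrema toward 0/1, leaving isolated spikes whose gradients would
dominate the solve. Second, when the estimated noise level exceeds
σ̂ = 0.02, only the strongest 10 % of latent gradients constrain the kernel;
under heavy speckle an unmasked solve walks the kernel into the trivial
delta (no-blur) solution, while on clean data every gradient is informative
and masking would discard constraints.

**Noise adaptation.** The gradient-L0 weight used by the image step and the
final restoration is `λ_g = grad_weight + 2σ̂²`, with σ̂ the wavelet-based
robust noise estimate of the observation. A fixed `4e−3` is calibrated for
clean images; at 20 dB speckle (σ̂ ≈ 0.1) the threshold separating structure
from noise must scale with the noise variance, and without this adaptation
the restoration amplifies speckle instead of removing it.

**Final restoration** (`nonblind_deconvolve`) — gradient-L0 half-quadratic
deconvolution with the fixed estimated kernel on the edge-tapered
observation (penalty doubling to β = 16). An exact delta kernel
short-circuits to the identity: inverting the identity kernel is the
identity, and running the smoothing machinery would needlessly alter an
already-sharp image. At low noise (σ̂ ≤ 0.02) up to three refinement rounds
re-estimate the kernel from the restored image — a far better edge source
than the cartoon intermediates — each accepted only if the joint objective
does not increase; under heavy speckle refinement is skipped because the
restoration is dominated by denoising and would pull the kernel to a delta.

**Monotonicity.** Half-quadratic splitting with re-linearized selections is
not intrinsically monotone. At the finest pyramid level the solver records
the joint objective after each outer iteration and rolls back any update
that raises it by more than 1e−6 relative, stopping there; the recorded
trace is therefore non-increasing by construction, as an honest
early-stopping rule rather than a post-hoc filter.

**Boundary rule.** Fourier solves use circular convolution on edge-tapered
images (a cosine-ramp blend into a blurred copy over a kernel-width band).
The forward model and the objective's data term use direct convolution with
border-clipped, renormalized kernel mass, so constants are preserved and a
delta kernel is exactly the identity. Brute-force oracles in the tests
compare interiors only, excluding a border of kernel radius.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `phi` (φ) | 2.0 | ridge weight on the kernel |
| `vartheta` (ϑ) | 1.0 | global weight of the channel-prior block |
| `theta`, `zeta` (θ, ζ) | 4e−3 | dark / bright-complement L0 weights |
| `grad_weight` | 4e−3 | gradient-L0 weight (noise-adapted at run time) |
| `patch_size` | 15 px | extremum window; secondary channels use 2× radius |
| `kernel_size` | 15 px | estimated kernel side (odd) |
| `scale_factor` | 0.75 | pyramid downscale per level |
| `outer_iters` / `inner_iters` | 5 / 4 | alternations per level / splitting rounds |
| `kernel_threshold` | 0.05 | kernel pruning fraction of the maximum |

All intensities live in [0,1]; `MAX_I` for PSNR is 1.0. These magnitudes
are conventional for extreme-channel deblurring; nothing here is tuned to a
particular image, and every default is overridable through `DeblurConfig`
or the YAML config of the CLI.

## Quality metrics

MSE is the plain per-pixel mean squared difference. PSNR is
`10·log10(MAX_I²/MSE)` with an infinite sentinel when MSE = 0. Quality
bands: > 40 dB excellent, 30–40 dB good, 20–30 dB poor, < 20 dB
unacceptable; 30 and 20 dB are assigned upward, and exactly 40 dB is
"good" because excellence requires strictly more than 40.

SSIM uses the canonical parameterization: 11×11 Gaussian window (σ = 1.5),
stabilizers C₁ = (0.01·L)², C₂ = (0.03·L)², C₃ = C₂/2 with L = `max_i`,
exponents (α, β, γ) = (1, 1, 1), under which the three-term product reduces
to the familiar two-term form; windows are fully interior ('valid').
SSIM is frequently described as lying in [0, 1], but the structure term can
be negative and negative values are reported as computed.

## The synthetic phantom benchmark

`nerve_region` sketches a femoral nerve-block field of view: a mid-gray
textured background, two near-saturated curved fascia bands, a hypoechoic
circular vessel lumen (< 0.05 intensity), and an echogenic nerve
cross-section with a bright rim and a honeycomb of dark fascicles. At least
1 % of pixels are < 0.05 and 1 % are > 0.95 by construction, so the channel
priors are active. `bars` (piecewise-constant stripes) and `blobs` (smooth
Gaussian bumps) support edge-position and degradation-ordering tests.

Degradation applies blur first (probe/tissue motion during acquisition),
then multiplicative unit-mean speckle, then clipping. `speckle_snr_db` is
referenced to full-scale intensity — it is the expected PSNR of the
speckled image against its clean input (realized within ~0.5 dB on ≥ 64²
images, before clipping effects at the intensity extremes). A unit-mean
Rayleigh multiplier has the fixed variance 4/π − 1, so the Rayleigh model
scales the centered fluctuation to hit the target; the Gamma model uses
shape k = 1/variance directly. Every pair regenerates bit-identically from
its spec or manifest row.

The standard suite — 20 pairs, 128×128 nerve scenes, motion kernels of
length 5–9 at seeded random angles inside a 9×9 support, Rayleigh speckle
at 20 dB — is what the statistical deblurring tests and the acceptance
script run on. Problem sizes (128² images, 20 seeds, 11×11 estimated
kernels for recovery tests) were chosen as the smallest suite on which the
statistical contracts are stable across seeds.

What the phantom does **not** emulate: coherent wave propagation and
interference (true speckle is correlated and depth-dependent), attenuation,
scan-conversion geometry, anatomical variability. Passing these tests shows
the estimator recovers known kernels and improves fidelity under the stated
degradation model — not that it improves clinical ultrasound.

## Clinical summary statistics

The clinical module works from printed group-level data only (no
per-patient records exist): ordered outcome counts, complication counts by
type, and mean ± SD endpoint summaries for a two-arm femoral nerve-block
study with 25 patients per arm (bundled as `data/clinical_groups.csv`).
Effective rate is 100·(effective + markedly effective)/n to one decimal;
complication rate is 100·(total complications)/n. The χ² test is Pearson's
on the 2×2 table without continuity correction (Yates available as an
option), p from χ² with 1 df; the t test reconstructs the classical
pooled-variance two-sample statistic from summaries (Welch optional).

Recomputing from the bundled counts: 92.0 % vs 80.0 % gives χ² = 1.495,
p = 0.221, and 8.0 % vs 16.0 % gives χ² = 0.758, p = 0.384 — neither is
significant at 0.05 even though such tables are often reported as
significant; the report prints the computed values and flags this rather
than suppressing it. The block-duration t tests are decisive
(sensory 7.53 ± 1.47 h vs 3.38 ± 1.26 h: t = 10.72, p ≈ 2.5e−14).

## Known limitations

- **Over-sharpening on mid-gray sharp scenes.** The channel prior pulls
  window extrema toward 0/1 unconditionally; on a blur-free image whose
  plateaus sit at intermediate gray this etches a faint contrast halo that
  the kernel step partially attributes to blur, leaving a small spurious
  kernel component (center mass 0.2–0.55; the restored image still scores
  26–41 dB against the input). Binary-contrast scenes are exact fixed
  points of the prior and recover a perfect delta. This degeneracy — the
  prior rewarding contrast beyond the true image — is shared by
  extreme-channel objectives generally.
- Smooth scenes are fundamentally ambiguous for blind deconvolution (a
  smooth image is indistinguishable from a blurred sharper one), and blur
  along the direction of translation-invariant structure is unobservable;
  kernel accuracy claims hold for scenes with two-dimensional structure.
- Speckle is treated as independent multiplicative noise; the solver's data
  term is least-squares, not a Rayleigh likelihood.
- Uniform (spatially invariant) blur only; no GPU path; no learned
  components.
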