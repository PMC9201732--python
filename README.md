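# echodeblur

Blind deblurring of speckle-corrupted ultrasound images with secondary
sparse extreme-channel priors, plus the evaluation stack (PSNR/SSIM with
quality bands), a ground-truthed synthetic phantom benchmark, and summary
statistics for two-arm clinical outcome tables.

## The problem

Ultrasound-guided nerve-block procedures depend on image quality, but
breathing, blood flow, and probe motion blur the image and add speckle.
Only the degraded observation `Z` is available; the sharp image `M` and the
blur kernel `h` must both be estimated (*blind* deconvolution). The key
observation exploited here: sharp nerve-region ultrasound contains
genuinely dark pixels (vessel lumens) and genuinely bright pixels (fascia).
Blur averages those extremes toward gray, so sparsity of the **dark
channel** `A_M(u) = min_{v∈φ(u)} M(v)` and of the **bright-channel
complement** `1 − Z_M(u)`, each applied twice ("secondary sparse", `S(·)`),
discriminates sharp from blurred images. The estimator minimizes

    ‖M ⊗ h − Z‖₂² + φ‖h‖₂² + ϑ·[θ·L0(S(A_M)) + ζ·L0(1 − S(Z_M))] + λ_g·L0(∇M)

by alternating half-quadratic image updates and ridge/IRLS kernel solves
over a coarse-to-fine pyramid, finishing with a non-blind gradient-L0
restoration. See `docs/methods.md` for the full algorithm, parameter table,
and known limitations.

## Worked example

```python
import echodeblur as ed

# a ground-truthed degraded phantom: 128x128 nerve-region scene,
# motion blur, Rayleigh speckle at 20 dB
pair = ed.generate_pair(ed.PhantomSpec(seed=1))

res = ed.multiscale_deblur(pair.observed, ed.DeblurConfig(seed=1))

for name, img in [("observed", pair.observed), ("restored", res.latent)]:
    rep = ed.evaluate_pair(pair.truth, img)
    print(f"{name} : psnr {rep.psnr:6.2f} dB  ssim {rep.ssim:.3f}  grade {rep.grade}")
print(f"true kernel: motion, length {pair.motion_length:.1f} px at {pair.motion_angle_deg:.0f} deg")
print(f"objective trace: {[round(v, 1) for v in res.objective_trace]}")
```

prints

```
observed : psnr  18.93 dB  ssim 0.264  grade unacceptable
restored : psnr  21.99 dB  ssim 0.819  grade poor
true kernel: motion, length 6.3 px at 110 deg
objective trace: [290.6, 269.3, 264.9, 264.1, 260.9]
```

The restoration gains ~3 dB PSNR and triples SSIM against the known ground
truth; the recorded joint objective decreases monotonically across the
outer iterations. `res.kernel` holds the estimated point-spread function
(unit mass, center-of-mass aligned).

The same pipeline is scriptable from the shell:

```sh
echodeblur simulate --n 20 --seed 0 --out suite/        # benchmark + manifest
echodeblur deblur --input suite/pair000_observed.png \
                  --output restored.png --kernel-out kernel --seed 0
echodeblur evaluate --benchmark-dir suite/ --out table.csv
echodeblur channels --input suite/pair000_observed.png --out-dir channels/
echodeblur report                                       # clinical summary table
```

`evaluate` writes the per-image `mse, psnr_db, ssim, grade` table; `report`
recomputes nursing effective rates (92.0 % vs 80.0 %), complication rates
(8.0 % vs 16.0 %), χ² and pooled-t statistics from the bundled printed
study table, flagging comparisons that do not reach p < 0.05 when
recomputed from the counts.

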