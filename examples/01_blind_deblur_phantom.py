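"""Blind-deblur one synthetic nerve-region phantom and score the result.

Builds a ground-truthed degraded pair (motion blur + 20 dB Rayleigh
speckle), runs the multiscale blind estimator, and prints PSNR/SSIM of the
observed and restored images against the known truth — the gain is what
the blind pipeline recovered without ever seeing the truth or the kernel.
"""

import echodeblur as ed

pair = ed.generate_pair(ed.PhantomSpec(seed=1))
res = ed.multiscale_deblur(pair.observed, ed.DeblurConfig(seed=1))

for name, img in [("observed", pair.observed), ("restored", res.latent)]:
    rep = ed.evaluate_pair(pair.truth, img)
    print(f"{name:9s}: psnr {rep.psnr:6.2f} dB  ssim {rep.ssim:.3f}  grade {rep.grade}")
print(f"true kernel: motion, length {pair.motion_length:.1f} px at "
      f"{pair.motion_angle_deg:.0f} deg; estimated support {res.kernel.support} px")
print("objective trace (non-increasing):",
      [round(v, 1) for v in res.objective_trace])
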