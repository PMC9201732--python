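import numpy as np
import pytest

import echodeblur as ed
from echodeblur.blind_deblur import edge_taper, psf2otf
from echodeblur.image_model import ParameterError, SolverError

from conftest import brute_convolve_interior, kernel_ncc


@pytest.fixture
def binary_checker():
    t = (np.indices((96, 96)).sum(0) // 12) % 2
    return ed.UltrasoundImage(t.astype(float))


class TestObjectiveValue:
    def test_exact_fit_no_penalties_is_zero(self):
        img = ed.UltrasoundImage(np.full((16, 16), 0.5))
        cfg = ed.DeblurConfig(phi=0, vartheta=0, theta=0, zeta=0, grad_weight=0)
        assert ed.objective_value(img, ed.BlurKernel.delta(3), img, cfg) == 0.0

    def test_data_term_matches_brute_force_interior(self, rng):
        latent = ed.UltrasoundImage(rng.uniform(size=(8, 8)))
        observed = ed.UltrasoundImage(rng.uniform(size=(8, 8)))
        k = ed.BlurKernel.from_array(rng.uniform(size=(3, 3)), normalize=True)
        conv = brute_convolve_interior(latent.pixels, k.weights)
        interior = ~np.isnan(conv)
        expected = np.sum((conv[interior] - observed.pixels[interior]) ** 2)
        got_conv = ed.apply_blur(latent, k).pixels
        got = np.sum((got_conv[interior] - observed.pixels[interior]) ** 2)
        assert abs(got - expected) < 1e-12

    def test_kernel_ridge_adds_phi_for_delta(self):
        img = ed.UltrasoundImage(np.full((16, 16), 0.5))
        base = ed.DeblurConfig(phi=0, vartheta=0, theta=0, zeta=0, grad_weight=0)
        with_phi = ed.DeblurConfig(phi=3.5, vartheta=0, theta=0, zeta=0, grad_weight=0)
        delta = ed.BlurKernel.delta(3)
        diff = ed.objective_value(img, delta, img, with_phi) - ed.objective_value(
            img, delta, img, base
        )
        assert abs(diff - 3.5) < 1e-12  # ||delta||^2 == 1

    def test_shape_mismatch(self):
        cfg = ed.DeblurConfig()
        with pytest.raises(ParameterError):
            ed.objective_value(
                ed.UltrasoundImage(np.zeros((8, 8))),
                ed.BlurKernel.delta(3),
                ed.UltrasoundImage(np.zeros((9, 9))),
                cfg,
            )


class TestEstimateLatent:
    def test_exact_recovery_delta_kernel_no_priors(self, small_phantom):
        cfg = ed.DeblurConfig(theta=0, zeta=0, grad_weight=0)
        out = ed.estimate_latent(small_phantom, ed.BlurKernel.delta(3), cfg)
        assert np.abs(out.pixels - small_phantom.pixels).max() < 1e-9

    @pytest.mark.parametrize("kernel", [
        ed.BlurKernel.gaussian(7, 1.5), ed.BlurKernel.motion(9, 7, 40)
    ])
    def test_constant_input_stays_constant(self, kernel):
        observed = ed.UltrasoundImage(np.full((64, 64), 0.4))
        out = ed.estimate_latent(observed, kernel, ed.DeblurConfig())
        assert out.pixels.max() - out.pixels.min() <= 1e-6

    def test_known_kernel_sharpening_improves_psnr(self):
        spec = ed.PhantomSpec(size=(64, 64), seed=5, speckle_model="none",
                              kernel_type="motion", kernel_size=7)
        pair = ed.generate_pair(spec)
        latent = ed.estimate_latent(pair.observed, pair.kernel, ed.DeblurConfig())
        assert ed.psnr(pair.truth, latent) > ed.psnr(pair.truth, pair.observed)

    def test_output_clipped(self, rng):
        observed = ed.UltrasoundImage(rng.uniform(size=(48, 48)))
        out = ed.estimate_latent(observed, ed.BlurKernel.gaussian(5, 1.0), ed.DeblurConfig())
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestEstimateKernel:
    def test_no_blur_gives_concentrated_delta(self, nerve_phantom):
        k = ed.estimate_kernel(nerve_phantom, nerve_phantom, ed.DeblurConfig(), kernel_size=9)
        assert k.weights[k.center] >= 0.9

    def test_known_gaussian_recovered(self, nerve_phantom):
        truth = ed.BlurKernel.gaussian(5, 1.0)
        blurred = ed.apply_blur(nerve_phantom, truth)
        est = ed.estimate_kernel(nerve_phantom, blurred, ed.DeblurConfig(), kernel_size=5)
        assert kernel_ncc(truth.weights, est.weights) >= 0.95

    def test_projection_guarantees_invariants(self, rng, nerve_phantom):
        blurred = ed.apply_blur(nerve_phantom, ed.BlurKernel.motion(9, 6, 120))
        k = ed.estimate_kernel(nerve_phantom, blurred, ed.DeblurConfig(), kernel_size=11)
        assert k.weights.min() >= 0.0
        assert abs(k.weights.sum() - 1.0) < 1e-8

    def test_degenerate_latent_raises(self):
        const = ed.UltrasoundImage(np.full((64, 64), 0.5))
        with pytest.raises(SolverError):
            ed.estimate_kernel(const, const, ed.DeblurConfig(), kernel_size=9)


class TestNonblindDeconvolve:
    def test_delta_kernel_is_identity(self, small_phantom):
        out = ed.nonblind_deconvolve(small_phantom, ed.BlurKernel.delta(5), ed.DeblurConfig())
        assert np.array_equal(out.pixels, small_phantom.pixels)

    def test_known_blur_gain_nonnegative_and_clipped(self):
        pair = ed.generate_pair(
            ed.PhantomSpec(seed=2, speckle_model="none", kernel_type="motion")
        )
        out = ed.nonblind_deconvolve(pair.observed, pair.kernel, ed.DeblurConfig())
        assert ed.psnr(pair.truth, out) >= ed.psnr(pair.truth, pair.observed)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestMultiscaleDeblur:
    def test_self_recovery_on_sharp_binary_scene(self, binary_checker):
        res = ed.multiscale_deblur(binary_checker, ed.DeblurConfig(kernel_size=9))
        assert res.kernel.weights[res.kernel.center] >= 0.9
        assert ed.psnr(binary_checker, res.latent) >= 40.0

    def test_blind_recovery_improves_speckled_phantom(self):
        pair = ed.generate_pair(ed.PhantomSpec(seed=1))
        res = ed.multiscale_deblur(pair.observed, ed.DeblurConfig(seed=1))
        gain = ed.psnr(pair.truth, res.latent) - ed.psnr(pair.truth, pair.observed)
        assert gain >= 2.0

    def test_objective_trace_monotone_and_finite(self):
        pair = ed.generate_pair(ed.PhantomSpec(seed=3))
        res = ed.multiscale_deblur(pair.observed, ed.DeblurConfig(seed=3))
        trace = np.array(res.objective_trace)
        assert len(trace) >= 1 and np.all(np.isfinite(trace))
        assert np.all(trace[1:] <= trace[:-1] * (1 + 1e-6))

    def test_deterministic_given_config(self):
        pair = ed.generate_pair(ed.PhantomSpec(seed=4))
        cfg = ed.DeblurConfig(seed=4)
        r1 = ed.multiscale_deblur(pair.observed, cfg)
        r2 = ed.multiscale_deblur(pair.observed, cfg)
        assert np.array_equal(r1.latent.pixels, r2.latent.pixels)
        assert np.array_equal(r1.kernel.weights, r2.kernel.weights)
        assert r1.objective_trace == r2.objective_trace

    def test_per_level_kernels_satisfy_invariants(self):
        pair = ed.generate_pair(ed.PhantomSpec(seed=5, speckle_model="none"))
        res = ed.multiscale_deblur(pair.observed, ed.DeblurConfig(seed=5))
        assert len(res.per_level_kernels) >= 1
        for k in res.per_level_kernels:
            assert k.weights.min() >= 0.0
            assert abs(k.weights.sum() - 1.0) < 1e-8
            assert k.support % 2 == 1

    @pytest.mark.parametrize("make_input", [
        lambda rng: np.full((64, 64), 0.5),
        lambda rng: rng.uniform(size=(64, 64)),
    ])
    def test_degenerate_inputs_terminate_finite(self, rng, make_input):
        img = ed.UltrasoundImage(make_input(rng))
        res = ed.multiscale_deblur(img, ed.DeblurConfig(kernel_size=9))
        assert np.all(np.isfinite(res.latent.pixels))
        assert np.all(np.isfinite(res.kernel.weights))

    def test_shift_equivariance_modulo_alignment(self):
        from scipy.signal import fftconvolve

        pair = ed.generate_pair(ed.PhantomSpec(seed=2, speckle_model="none"))
        cfg = ed.DeblurConfig(seed=2, kernel_size=11)
        r1 = ed.multiscale_deblur(pair.observed, cfg)
        shifted = ed.UltrasoundImage(np.roll(pair.observed.pixels, (5, 7), (0, 1)))
        r2 = ed.multiscale_deblur(shifted, cfg)
        a = r1.latent.pixels - r1.latent.pixels.mean()
        b = np.roll(r2.latent.pixels, (-5, -7), (0, 1))
        b = b - b.mean()
        corr = fftconvolve(a, b[::-1, ::-1], mode="full")
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        offset = (peak[0] - (a.shape[0] - 1), peak[1] - (a.shape[1] - 1))
        assert max(abs(offset[0]), abs(offset[1])) <= 1
        assert corr.max() / (np.linalg.norm(a) * np.linalg.norm(b)) >= 0.95

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            ed.multiscale_deblur(ed.UltrasoundImage(np.zeros((16, 16))), ed.DeblurConfig())


class TestFourierHelpers:
    def test_psf2otf_matches_circular_convolution(self, rng):
        img = rng.uniform(size=(16, 16))
        k = ed.BlurKernel.gaussian(5, 1.0)
        via_otf = np.real(np.fft.ifft2(np.fft.fft2(img) * psf2otf(k.weights, img.shape)))
        from scipy.ndimage import convolve

        direct = convolve(img, k.weights, mode="wrap")
        assert np.allclose(via_otf, direct, atol=1e-12)

    def test_edge_taper_preserves_interior(self, nerve_phantom):
        k = ed.BlurKernel.gaussian(9, 2.0)
        tapered = edge_taper(nerve_phantom.pixels, k)
        assert np.array_equal(tapered[16:-16, 16:-16], nerve_phantom.pixels[16:-16, 16:-16])
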