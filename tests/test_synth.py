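import numpy as np
import pytest

import echodeblur as ed
from echodeblur.image_model import ParameterError
from echodeblur.synth import make_kernel, pair_from_manifest_row

from conftest import brute_convolve_interior


class TestPhantomScenes:
    def test_seeded_determinism(self):
        spec = ed.PhantomSpec(seed=11)
        assert np.array_equal(ed.make_phantom(spec).pixels, ed.make_phantom(spec).pixels)

    def test_nerve_region_has_genuine_extremes(self):
        for seed in range(5):
            img = ed.make_phantom(ed.PhantomSpec(seed=seed))
            frac_dark = (img.pixels < 0.05).mean()
            frac_bright = (img.pixels > 0.95).mean()
            assert frac_dark >= 0.01
            assert frac_bright >= 0.01

    def test_bars_piecewise_constant_with_known_edges(self):
        img = ed.make_phantom(ed.PhantomSpec(scene="bars", seed=0))
        bar = img.width // 8
        cols = img.pixels[0]
        assert np.array_equal(img.pixels, np.tile(cols, (img.height, 1)))
        for j in range(0, img.width - bar, bar):
            assert np.all(cols[j: j + bar] == cols[j])
            assert cols[j] != cols[j + bar]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            ed.PhantomSpec(size=(16, 16))
        with pytest.raises(ParameterError):
            ed.PhantomSpec(scene="nope")
        with pytest.raises(ParameterError):
            ed.PhantomSpec(kernel_size=33)  # >= min(size)/4


class TestApplyBlur:
    def test_delta_identity(self, small_phantom):
        out = ed.apply_blur(small_phantom, ed.BlurKernel.delta(5))
        assert np.array_equal(out.pixels, small_phantom.pixels)

    def test_constant_preserved(self):
        img = ed.UltrasoundImage(np.full((32, 32), 0.37))
        out = ed.apply_blur(img, ed.BlurKernel.gaussian(7, 2.0))
        assert np.allclose(out.pixels, 0.37)

    def test_interior_matches_nested_loops(self, rng):
        img = ed.UltrasoundImage(rng.uniform(size=(8, 8)))
        k = ed.BlurKernel.from_array(rng.uniform(size=(3, 3)), normalize=True)
        expected = brute_convolve_interior(img.pixels, k.weights)
        got = ed.apply_blur(img, k).pixels
        interior = ~np.isnan(expected)
        assert np.allclose(got[interior], expected[interior], atol=1e-12)

    def test_kernel_larger_than_image_rejected(self):
        img = ed.UltrasoundImage(np.zeros((8, 8)))
        with pytest.raises(ParameterError):
            ed.apply_blur(img, ed.BlurKernel.delta(9))


class TestAddSpeckle:
    def test_none_model_is_identity(self, small_phantom):
        assert ed.add_speckle(small_phantom, "none", 20.0, 0) is small_phantom

    def test_seeded_reproducibility(self, small_phantom):
        a = ed.add_speckle(small_phantom, "rayleigh", 20.0, 42)
        b = ed.add_speckle(small_phantom, "rayleigh", 20.0, 42)
        assert np.array_equal(a.pixels, b.pixels)
        c = ed.add_speckle(small_phantom, "rayleigh", 20.0, 43)
        assert not np.array_equal(a.pixels, c.pixels)

    @pytest.mark.parametrize("model", ["rayleigh", "gamma"])
    def test_realized_snr_near_target(self, model):
        img = ed.UltrasoundImage(np.full((128, 128), 0.5))
        for snr in (40.0, 20.0):
            noisy = ed.add_speckle(img, model, snr, 7)
            assert abs(ed.psnr(img, noisy) - snr) < 0.5

    def test_forty_db_on_midgray_lands_in_psnr_band(self):
        img = ed.UltrasoundImage(np.full((64, 64), 0.5))
        noisy = ed.add_speckle(img, "rayleigh", 40.0, 3)
        assert 35.0 < ed.psnr(img, noisy) < 45.0

    def test_unknown_model_rejected(self, small_phantom):
        with pytest.raises(ParameterError):
            ed.add_speckle(small_phantom, "poisson", 20.0, 0)


class TestBenchmarkSuite:
    def test_manifest_written_and_regenerable(self, tmp_path):
        manifest = ed.make_benchmark_suite(tmp_path, n=3, base_seed=5)
        assert len(manifest) == 3
        assert list(manifest["seed"]) == [5, 6, 7]
        assert (tmp_path / "manifest.csv").exists()
        for _, row in manifest.iterrows():
            pair = pair_from_manifest_row(row)
            stored = ed.read_image(tmp_path / f"{row['pair']}_truth.png")
            quantized = np.round(pair.truth.pixels * 65535) / 65535
            assert np.abs(stored.pixels - quantized).max() < 1e-9
            kernel = np.loadtxt(tmp_path / f"{row['pair']}_kernel.txt")
            assert np.allclose(kernel, pair.kernel.weights)

    def test_degradation_is_real(self, tmp_path):
        manifest = ed.make_benchmark_suite(tmp_path, n=3, base_seed=0)
        assert (manifest["psnr_observed_db"] < 35.0).all()

    def test_generate_pair_bit_reproducible(self):
        spec = ed.PhantomSpec(seed=9)
        p1, p2 = ed.generate_pair(spec), ed.generate_pair(spec)
        assert np.array_equal(p1.observed.pixels, p2.observed.pixels)
        assert np.array_equal(p1.kernel.weights, p2.kernel.weights)
        assert p1.motion_angle_deg == p2.motion_angle_deg

    def test_default_suite_conditions(self):
        suite = ed.default_suite(n=2, base_seed=0)
        for pair in suite:
            assert pair.spec.scene == "nerve_region"
            assert pair.spec.size == (128, 128)
            assert pair.spec.speckle_model == "rayleigh"
            assert pair.spec.speckle_snr_db == 20.0
            assert 5.0 <= pair.motion_length <= 9.0


class TestDegradationOrdering:
    def test_wider_blur_never_raises_psnr(self):
        # 10-seed average over increasing Gaussian blur width, fixed noise
        sigmas = [0.8, 1.5, 2.5]
        means = []
        for sigma in sigmas:
            vals = []
            for seed in range(10):
                truth = ed.make_phantom(ed.PhantomSpec(seed=seed))
                blurred = ed.apply_blur(truth, ed.BlurKernel.gaussian(9, sigma))
                vals.append(ed.psnr(truth, blurred))
            means.append(np.mean(vals))
        assert all(x >= y for x, y in zip(means, means[1:]))


def test_motion_kernel_realization_recorded():
    spec = ed.PhantomSpec(seed=4, motion_length=7.0, motion_angle_deg=30.0)
    kernel, length, angle = make_kernel(spec)
    assert (length, angle) == (7.0, 30.0)
    spec2 = ed.PhantomSpec(seed=4)
    _, length2, angle2 = make_kernel(spec2)
    assert 5.0 <= length2 <= 9.0 and 0.0 <= angle2 <= 180.0
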