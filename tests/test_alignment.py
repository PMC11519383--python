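"""Angular spectrum, alignment coefficient, orientation and density."""

import numpy as np
import pytest

from fibralign import (
    FiberFieldParams,
    OrientationSpectrum,
    alignment_coefficient,
    analyze_image,
    angular_spectrum,
    dominant_orientation,
    fiber_density,
    generate_fiber_image,
    true_alignment,
)
from fibralign.alignment import DegenerateImageError, DegenerateSpectrumError
from fibralign.preprocess import EnhancedImage


def spectrum(theta, energy):
    return OrientationSpectrum(theta_bins=np.asarray(theta, float),
                               energy=np.asarray(energy, float),
                               radial_band=(0.05, 0.45))


def brute_force_angular_spectrum(img, r_min, r_max, n_bins):
    """Independent oracle: explicit DFT matrices and loop-based binning."""
    sq = np.asarray(img, float)
    n = sq.shape[0]
    sq = sq - sq.mean()
    win = np.hanning(n)
    sq = sq * win[:, None] * win[None, :]
    j = np.arange(n)
    E = np.exp(-2j * np.pi * np.outer(j, j) / n)  # DFT matrix, not np.fft
    F = E @ sq @ E
    power = np.abs(F) ** 2
    energy = np.zeros(n_bins)
    for r in range(n):
        for c in range(n):
            fy = (r - n) / n if r > n // 2 else r / n
            fx = (c - n) / n if c > n // 2 else c / n
            rad = np.hypot(fx, fy) / 0.5
            if rad <= 0 or rad < r_min or rad > r_max:
                continue
            theta = (np.arctan2(fy, fx) + np.pi / 2) % np.pi
            energy[min(int(theta / np.pi * n_bins), n_bins - 1)] += power[r, c]
    return energy


class TestAngularSpectrum:
    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32))
        spec = angular_spectrum(img, 0.1, 0.45, 36)
        oracle = brute_force_angular_spectrum(img, 0.1, 0.45, 36)
        assert np.allclose(spec.energy, oracle, rtol=1e-8)

    def test_horizontal_stripes_concentrate_at_zero(self):
        """Row-wise sinusoid = horizontal fiber axis; energy within ±5° of 0."""
        n = 128
        rows = np.arange(n)[:, None]
        # 20 cycles: the Hann main lobe spans ±1 frequency bin, i.e.
        # atan(1/20) ≈ 2.9° about the vertical spectral axis
        img = 0.5 + 0.5 * np.cos(2 * np.pi * 20 * rows / n) * np.ones((1, n))
        spec = angular_spectrum(img, 0.05, 0.45, 180)
        near = (spec.theta_bins <= np.deg2rad(5)) | \
               (spec.theta_bins >= np.pi - np.deg2rad(5))
        assert spec.energy[near].sum() / spec.total_energy >= 0.90

    def test_rotation_by_90_degrees(self):
        n = 128
        rows = np.arange(n)[:, None]
        img = 0.5 + 0.5 * np.cos(2 * np.pi * 20 * rows / n) * np.ones((1, n))
        spec = angular_spectrum(np.rot90(img), 0.05, 0.45, 180)
        dom = dominant_orientation(spec)
        assert abs(dom - np.pi / 2) < np.deg2rad(5)

    def test_white_noise_is_isotropic(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = angular_spectrum(rng.uniform(0, 1, (128, 128)))
            vals.append(alignment_coefficient(spec))
        assert np.mean(vals) < 0.1

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            angular_spectrum(np.full((64, 64), 0.5))

    def test_non_square_center_cropped(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (64, 96))
        spec = angular_spectrum(img)
        crop = img[:, 16:80]
        assert np.allclose(spec.energy, angular_spectrum(crop).energy)

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            angular_spectrum(np.eye(32), r_min=0.4, r_max=0.3)


class TestAlignmentCoefficient:
    def test_point_mass_is_exactly_one(self):
        bins = (np.arange(180) + 0.5) * np.pi / 180
        energy = np.zeros(180)
        energy[45] = 3.7  # all energy at one orientation
        assert alignment_coefficient(spectrum(bins, energy)) == 1.0

    def test_uniform_bins_exactly_zero(self):
        bins = (np.arange(180) + 0.5) * np.pi / 180
        assert alignment_coefficient(spectrum(bins, np.ones(180))) == 0.0

    def test_half_split_closed_form(self):
        spec = spectrum([0.0, np.pi / 4], [1.0, 1.0])
        assert alignment_coefficient(spec) == pytest.approx(np.sqrt(2) / 2,
                                                            abs=1e-12)

    def test_zero_energy_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            alignment_coefficient(spectrum([0.0, 1.0], [0.0, 0.0]))


class TestDominantOrientation:
    def test_point_mass(self):
        assert dominant_orientation(spectrum([np.pi / 3], [2.0])) == \
            pytest.approx(np.pi / 3)

    def test_balanced_axes_undefined(self):
        with pytest.raises(DegenerateSpectrumError):
            dominant_orientation(spectrum([0.0, np.pi / 2], [1.0, 1.0]))

    def test_weighted_mean_two_to_one(self):
        # doubled-angle resultant 2·e^{0} + 1·e^{iπ} = 1 → orientation 0
        assert dominant_orientation(spectrum([0.0, np.pi / 2], [2.0, 1.0])) == \
            pytest.approx(0.0, abs=1e-12)


class TestFiberDensity:
    def test_blank_and_counting(self):
        assert fiber_density(np.zeros((8, 8))) == 0.0
        img = np.zeros((8, 8))
        img[:4, :4] = 0.7
        assert fiber_density(img) == 0.25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fiber_density(np.zeros((0, 0)))

    def test_union_never_decreases_density(self):
        rng = np.random.default_rng(4)
        a = (rng.uniform(size=(32, 32)) > 0.8) * 0.5
        b = (rng.uniform(size=(32, 32)) > 0.8) * 0.9
        union = np.maximum(a, b)
        assert fiber_density(union) >= max(fiber_density(a), fiber_density(b))


class TestAnalyzeImage:
    def test_blank_image_degenerate(self):
        params = FiberFieldParams(image_size=64, n_fibers=0)
        image, _ = generate_fiber_image(params)
        with pytest.raises(DegenerateImageError):
            analyze_image(image)

    def test_aligned_field_matches_oracle(self, aligned_field):
        params, image, truth = aligned_field
        res = analyze_image(image)
        oracle = true_alignment(truth.orientations)
        assert res.coefficient >= 0.8
        assert abs(res.coefficient - oracle) <= 0.15
        assert abs(res.dominant_orientation - params.mean_orientation) < \
            np.deg2rad(5)

    def test_isotropic_field_low_coefficient(self):
        vals = []
        for seed in range(10):
            params = FiberFieldParams(image_size=256, n_fibers=300,
                                      concentration=0.0, seed=seed)
            image, _ = generate_fiber_image(params)
            vals.append(analyze_image(image).coefficient)
        assert np.mean(vals) <= 0.15

    def test_results_in_unit_intervals(self, aligned_field, isotropic_field):
        for _, image, _ in (aligned_field, isotropic_field):
            res = analyze_image(image)
            assert 0.0 <= res.coefficient <= 1.0
            assert 0.0 <= res.density <= 1.0
            assert 0.0 <= res.dominant_orientation < np.pi

    def test_downscale_robustness(self, aligned_field):
        """2× block-mean downsampling changes the coefficient by < 0.1."""
        _, image, _ = aligned_field
        res = analyze_image(image)
        small = image.astype(float).reshape(128, 2, 128, 2, 3).mean((1, 3))
        small = np.clip(np.rint(small), 0, 255).astype(np.uint8)
        assert abs(analyze_image(small).coefficient - res.coefficient) < 0.1

    def test_density_matches_enhancement_replay(self, aligned_field):
        """Density equals an independent non-zero recount of the enhanced map."""
        from fibralign import enhance, isolate_collagen, rgb_to_lab
        _, image, _ = aligned_field
        res = analyze_image(image)
        enh = enhance(isolate_collagen(rgb_to_lab(image)))
        recount = int(np.sum(enh.values > 0)) / enh.values.size
        assert res.density == recount
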