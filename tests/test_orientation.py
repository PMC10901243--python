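"""Tests for axial histogram statistics, peak finding, beta and gamma."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberpol import (
    axial_distance,
    beta,
    build_fdh,
    classify_peaks,
    find_peaks,
    gamma,
)
from fiberpol.orientation import ClassificationRefused, circular_mean, smooth_fdh


def wrapped_normal(rng, mu, sigma, n):
    return np.mod(rng.normal(mu, sigma, n), 180.0)


class TestAxialDistance:
    @pytest.mark.parametrize(
        "a,b,expected", [(0, 180, 0), (10, 100, 90), (170, 20, 30), (45, 45, 0)]
    )
    def test_examples(self, a, b, expected):
        assert abs(axial_distance(a, b) - expected) < 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(0, 359), b=st.integers(0, 359))
    def test_matches_brute_force_on_degree_grid(self, a, b):
        brute = min(abs((a - b + 180 * k)) for k in range(-3, 4))
        assert abs(axial_distance(a, b) - brute) < 1e-12

    def test_range(self):
        grid = np.arange(0, 180, 1.0)
        d = axial_distance(grid[:, None], grid[None, :])
        assert d.min() >= 0 and d.max() <= 90


class TestBuildFdh:
    def test_point_mass(self):
        fdh = build_fdh(np.full(1000, 45.0))
        assert fdh.mass.max() == 1.0
        assert fdh.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_per_degree(self):
        fdh = build_fdh(np.arange(0.0, 180.0))
        np.testing.assert_allclose(fdh.mass, 1 / 180)

    def test_wrapped_normal_circular_mean(self, rng):
        fdh = build_fdh(wrapped_normal(rng, 30.0, 8.0, 100_000))
        assert abs(circular_mean(fdh) - 30.0) < 0.2

    def test_mass_conserved_and_nonnegative(self, rng):
        fdh = build_fdh(rng.uniform(0, 180, 5000), bin_width=2.0)
        assert fdh.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fdh.mass >= 0)
        assert len(fdh.bin_centers) == 90

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_fdh(np.array([np.nan, np.nan]))

    def test_non_divisor_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_fdh(np.array([10.0]), bin_width=7.0)


class TestFindPeaks:
    def test_single_mode(self, rng):
        fdh = build_fdh(wrapped_normal(rng, 72.0, 6.0, 100_000))
        peaks = find_peaks(fdh)
        assert peaks.modality == 1
        assert axial_distance(peaks[0].angle, 72.0) <= 1.0

    def test_orthogonal_mixture_two_peaks(self, rng):
        n = 100_000
        comp = rng.random(n) < 0.6
        angles = np.where(comp, wrapped_normal(rng, 20.0, 6.0, n),
                          wrapped_normal(rng, 110.0, 6.0, n))
        peaks = find_peaks(build_fdh(angles))
        assert peaks.modality == 2
        assert axial_distance(peaks[0].angle, peaks[1].angle) >= 88.0

    def test_wraparound_peak_at_zero(self, rng):
        fdh = build_fdh(wrapped_normal(rng, 0.0, 5.0, 50_000))
        peaks = find_peaks(fdh)
        assert peaks.modality == 1
        assert axial_distance(peaks[0].angle, 0.0) <= 1.0

    def test_flat_histogram_no_peaks(self):
        fdh = build_fdh(np.arange(0.0, 180.0))
        assert find_peaks(fdh).modality == 0

    def test_peaks_sorted_by_density(self, rng):
        n = 80_000
        comp = rng.random(n) < 0.7
        angles = np.where(comp, wrapped_normal(rng, 40.0, 5.0, n),
                          wrapped_normal(rng, 130.0, 5.0, n))
        peaks = find_peaks(build_fdh(angles))
        assert peaks[0].density >= peaks[1].density
        assert axial_distance(peaks[0].angle, 40.0) <= 1.0


class TestBeta:
    def test_rectangular_bump(self):
        angles = np.repeat(np.arange(60.0, 80.0), 50)
        fdh = build_fdh(angles)
        b = beta(fdh, 70.0)
        assert abs(b - 20.0) <= 1.0

    def test_gaussian_fwhm(self, rng):
        fdh = build_fdh(wrapped_normal(rng, 90.0, 6.0, 100_000))
        assert abs(beta(fdh, 90.0) - 2.355 * 6.0) <= 1.0

    def test_fwhm_linear_in_sigma(self, rng):
        fdh = build_fdh(wrapped_normal(rng, 90.0, 12.0, 100_000))
        assert abs(beta(fdh, 90.0) - 2.355 * 12.0) <= 1.5

    def test_fwhm_accuracy_across_sigmas(self, rng):
        for sigma in (4.0, 7.0, 10.0, 15.0):
            fdh = build_fdh(wrapped_normal(rng, 60.0, sigma, 100_000))
            expected = 2.355 * sigma
            assert abs(beta(fdh, 60.0) - expected) <= 0.1 * expected

    def test_undefined_width_flagged(self):
        # uniform-ish mass never crosses half max: width undefined, not a crash
        fdh = build_fdh(np.arange(0.0, 180.0, 0.5))
        assert np.isnan(beta(fdh, 90.0))


class TestGamma:
    def test_equal_peaks(self):
        assert gamma(0.1, 0.1) == pytest.approx(0.5)

    def test_pure_intrinsic(self):
        assert gamma(0.2, 0.0) == 1.0

    def test_direct_arithmetic(self):
        assert gamma(0.12, 0.04) == pytest.approx(0.75)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gamma(0.0, 0.0)


class TestClassifyPeaks:
    def _mixture(self, rng, fiber, w, n=60_000, sigma=6.0):
        comp = rng.random(n) < w
        theta = np.where(
            comp,
            wrapped_normal(rng, fiber + 90.0, sigma, n),
            wrapped_normal(rng, fiber, sigma, n),
        )
        alpha = wrapped_normal(rng, fiber + 90.0, sigma, n)
        return build_fdh(theta), build_fdh(alpha)

    def test_form_only_sample_gamma_zero(self, rng):
        # glass-fiber-like: lone theta peak on the fiber axis, alphaP perpendicular
        theta_fdh = build_fdh(wrapped_normal(rng, 0.0, 4.0, 50_000))
        alpha_fdh = build_fdh(wrapped_normal(rng, 90.0, 4.0, 50_000))
        s = classify_peaks(find_peaks(theta_fdh), alpha_fdh)
        assert s.gamma == 0.0
        assert s.theta_b is None
        assert axial_distance(s.theta_c, 0.0) <= 1.0
        assert axial_distance(s.fiber_axis, 0.0) <= 1.0

    def test_intrinsic_only_sample_gamma_one(self, rng):
        # air-dried-tendon-like: lone theta peak perpendicular to the fiber
        theta_fdh = build_fdh(wrapped_normal(rng, 90.0, 4.0, 50_000))
        alpha_fdh = build_fdh(wrapped_normal(rng, 90.0, 4.0, 50_000))
        s = classify_peaks(find_peaks(theta_fdh), alpha_fdh)
        assert s.gamma == 1.0
        assert s.theta_c is None
        assert axial_distance(s.theta_b, 90.0) <= 1.0

    def test_bimodal_classification_and_gamma(self, rng):
        theta_fdh, alpha_fdh = self._mixture(rng, fiber=30.0, w=0.6)
        s = classify_peaks(find_peaks(theta_fdh), alpha_fdh)
        assert s.modality == 2
        assert axial_distance(s.theta_b, 120.0) <= 2.0
        assert axial_distance(s.theta_c, 30.0) <= 2.0
        assert abs(s.gamma - 0.6) <= 0.05
        assert axial_distance(s.theta_b, s.theta_c) >= 87.0

    def test_multimodal_alpha_refused(self, rng):
        theta_fdh, _ = self._mixture(rng, fiber=0.0, w=0.5)
        alpha_bimodal, _ = self._mixture(rng, fiber=45.0, w=0.5)
        with pytest.raises(ClassificationRefused):
            classify_peaks(find_peaks(theta_fdh), alpha_bimodal)

    def test_multipetal_theta_refused(self, rng):
        n = 80_000
        angles = np.concatenate(
            [wrapped_normal(rng, mu, 5.0, n // 4) for mu in (0, 45, 90, 135)]
        )
        alpha_fdh = build_fdh(wrapped_normal(rng, 90.0, 5.0, n))
        with pytest.raises(ClassificationRefused) as exc:
            classify_peaks(find_peaks(build_fdh(angles)), alpha_fdh)
        assert exc.value.theta_modality > 2


class TestInvariances:
    def test_translation_invariance_of_peaks_and_beta(self, rng):
        """Shifting all angles by phi shifts the peaks by phi with identical
        masses and widths."""
        n = 100_000
        comp = rng.random(n) < 0.6
        base = np.where(comp, wrapped_normal(rng, 20.0, 6.0, n),
                        wrapped_normal(rng, 110.0, 6.0, n))
        p0 = find_peaks(build_fdh(base))
        for phi in (33.0, 90.0, 151.0):
            p1 = find_peaks(build_fdh(np.mod(base + phi, 180.0)))
            assert p1.modality == p0.modality
            for a, b in zip(p0, p1):
                assert axial_distance(np.mod(a.angle + phi, 180.0), b.angle) < 1e-9
                assert a.density == pytest.approx(b.density, abs=1e-12)
                assert a.beta == pytest.approx(b.beta, abs=1e-9)

    def test_gamma_recovery_across_mixture_weights(self, rng):
        """|gamma_hat - w| <= 0.05 for w in {0.2,...,0.8} at n = 1e5."""
        n = 100_000
        for w in (0.2, 0.35, 0.5, 0.65, 0.8):
            comp = rng.random(n) < w
            theta = np.where(comp, wrapped_normal(rng, 90.0, 8.0, n),
                             wrapped_normal(rng, 0.0, 8.0, n))
            alpha_fdh = build_fdh(wrapped_normal(rng, 90.0, 8.0, n))
            s = classify_peaks(find_peaks(build_fdh(theta)), alpha_fdh)
            assert abs(s.gamma - w) <= 0.05

    def test_smoothing_preserves_mass(self, rng):
        fdh = build_fdh(rng.uniform(0, 180, 3000))
        sm = smooth_fdh(fdh, window=3)
        assert sm.mass.sum() == pytest.approx(1.0, abs=1e-9)
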