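import numpy as np
import pytest

from pericav.metrics import (ElementPeaks, accumulate_peaks,
                             exceedance_fraction, green_lagrange_principal,
                             max_shear_stress, rate_of_deformation_principal,
                             roi_percentile, summarize_rois)


class TestGreenLagrange:
    def test_identity_zero(self):
        assert green_lagrange_principal(np.eye(2)) == 0.0

    def test_uniaxial_stretch_closed_form(self):
        F = np.diag([1.2, 1.0])
        assert green_lagrange_principal(F) == pytest.approx((1.2**2 - 1) / 2)

    def test_simple_shear(self):
        F = np.array([[1.0, 0.5], [0.0, 1.0]])
        assert green_lagrange_principal(F) == pytest.approx(0.320194,
                                                            abs=1e-5)

    def test_left_rotation_invariance(self):
        rng = np.random.default_rng(5)
        F = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
        assert np.linalg.det(F) > 0
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert green_lagrange_principal(R @ F) == pytest.approx(
            green_lagrange_principal(F), rel=1e-12)

    def test_small_strain_consistency(self):
        eps = 1e-4
        F = np.array([[1 + eps, eps / 2], [eps / 2, 1.0]])
        small = np.linalg.eigvalsh(0.5 * (F + F.T) - np.eye(2))[-1]
        assert green_lagrange_principal(F) == pytest.approx(small,
                                                            abs=10 * eps**2)

    def test_batched_evaluation(self):
        F = np.stack([np.eye(2), np.diag([1.2, 1.0])])
        out = green_lagrange_principal(F)
        assert out.shape == (2,)
        assert out[1] == pytest.approx(0.22)

    def test_inverted_rejected(self):
        with pytest.raises(ValueError):
            green_lagrange_principal(np.diag([-1.0, 1.0]))


class TestRateOfDeformation:
    def test_zero(self):
        assert rate_of_deformation_principal(np.zeros((2, 2))) == 0.0

    def test_pure_spin_vanishes(self):
        W = np.array([[0.0, 5.0], [-5.0, 0.0]])
        assert rate_of_deformation_principal(W) == pytest.approx(0.0)

    def test_simple_shear_rate(self):
        L = np.array([[0.0, 10.0], [0.0, 0.0]])
        assert rate_of_deformation_principal(L) == pytest.approx(5.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rate_of_deformation_principal(np.array([[np.nan, 0], [0, 0]]))


class TestMaxShear:
    def test_hydrostatic_zero(self):
        assert max_shear_stress(100.0 * np.eye(3)) == pytest.approx(0.0)

    def test_uniaxial(self):
        s = np.zeros((3, 3))
        s[0, 0] = 100.0
        assert max_shear_stress(s) == pytest.approx(50.0)

    def test_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 1000.0
        assert max_shear_stress(s) == pytest.approx(1000.0)

    def test_asymmetric_rejected(self):
        s = np.zeros((3, 3))
        s[0, 1] = 1.0
        with pytest.raises(ValueError):
            max_shear_stress(s)


class TestPeaks:
    def test_running_maximum(self):
        hist = [([0.1], [1.0], [5.0]), ([0.5], [0.5], [2.0]),
                ([0.2], [2.0], [8.0])]
        peaks = accumulate_peaks(hist, area=[1.0])
        assert peaks.strain_peak[0] == 0.5
        assert peaks.rate_peak[0] == 2.0
        assert peaks.shear_stress_peak[0] == 8.0
        assert peaks.n_steps == 3

    def test_single_step(self):
        peaks = accumulate_peaks([([0.3], [1.0], [2.0])], area=[1.0])
        assert peaks.strain_peak[0] == 0.3

    def test_peaks_nondecreasing_with_more_steps(self):
        peaks = ElementPeaks.zeros(3, np.ones(3))
        rng = np.random.default_rng(2)
        prev = np.zeros(3)
        for _ in range(10):
            peaks.update(rng.uniform(0, 1, 3), np.zeros(3), np.zeros(3))
            assert np.all(peaks.strain_peak >= prev)
            prev = peaks.strain_peak.copy()

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            accumulate_peaks([], area=[1.0])


class TestROISummaries:
    def test_percentile_linear_interpolation(self):
        vals = np.arange(1.0, 101.0)
        labels = np.full(100, "roi")
        assert roi_percentile(vals, labels, "roi", 95) == pytest.approx(95.05)

    def test_constant_values(self):
        vals = np.full(10, 7.0)
        labels = np.full(10, "roi")
        assert roi_percentile(vals, labels, "roi", 37.5) == 7.0

    def test_q100_is_maximum(self):
        vals = np.array([3.0, 9.0, 1.0])
        labels = np.full(3, "roi")
        assert roi_percentile(vals, labels, "roi", 100) == 9.0

    def test_permutation_invariance_and_monotone_in_q(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(size=50)
        labels = np.full(50, "roi")
        perm = rng.permutation(50)
        assert roi_percentile(vals[perm], labels, "roi", 95) == pytest.approx(
            roi_percentile(vals, labels, "roi", 95))
        qs = [10, 30, 50, 70, 90, 95, 99]
        ps = [roi_percentile(vals, labels, "roi", q) for q in qs]
        assert np.all(np.diff(ps) >= 0)

    def test_unknown_roi_rejected(self):
        with pytest.raises(KeyError):
            roi_percentile([1.0, 2.0], np.array(["a", "a"]), "b")

    def test_exceedance_fractions(self):
        peaks = ElementPeaks(strain_peak=np.array([0.3, 0.1]),
                             rate_peak=np.array([40.0, 10.0]),
                             shear_stress_peak=np.zeros(2),
                             area=np.array([1.0, 1.0]))
        labels = np.array(["roi", "roi"])
        assert exceedance_fraction(peaks, labels, "roi", 0.2,
                                   "strain") == 0.5
        assert exceedance_fraction(peaks, labels, "roi", 0.0, "strain") == 1.0
        assert exceedance_fraction(peaks, labels, "roi", 1.0, "strain") == 0.0
        # area weighting
        peaks.area[:] = [3.0, 1.0]
        assert exceedance_fraction(peaks, labels, "roi", 0.2,
                                   "strain") == 0.75

    def test_summaries_consistent_with_components(self):
        rng = np.random.default_rng(4)
        n = 40
        peaks = ElementPeaks(strain_peak=rng.uniform(0, 0.4, n),
                             rate_peak=rng.uniform(0, 60, n),
                             shear_stress_peak=rng.uniform(0, 100, n),
                             area=np.ones(n))
        labels = np.where(np.arange(n) < 25, "a", "b")
        summ = summarize_rois(peaks, labels)
        assert set(summ) == {"a", "b"}
        assert summ["a"].n_elements == 25
        assert summ["a"].strain_p95 <= peaks.strain_peak[labels == "a"].max()
        assert 0 <= summ["b"].exceed_rate_frac <= 1
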