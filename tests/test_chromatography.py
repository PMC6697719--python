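"""Quantification stage: baseline, detection, normalization, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chargevar as cv
from chargevar.chromatography import (
    correct_baseline,
    detect_peaks,
    estimate_noise_sd,
    normalize_retention,
    select_main_peak,
)
from chargevar.errors import CalibrationError, NoPeaksError, ValidationError


def make_trace(time, absorbance, **kw):
    return cv.Chromatogram(time=time, absorbance=absorbance, **kw)


def gaussian(t, center, sigma, area):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - center) / sigma) ** 2)


T = np.arange(0.0, 35.0, 0.01)


class TestBaseline:
    def test_flat_offset_removed(self):
        out = correct_baseline(make_trace(T, np.full_like(T, 0.3)))
        assert np.allclose(out.absorbance, 0.0, atol=1e-12)
        assert out.baseline_corrected

    def test_linear_ramp_removed(self):
        out = correct_baseline(make_trace(T, 0.4 * T / T[-1]))
        assert np.allclose(out.absorbance, 0.0, atol=1e-9)

    def test_peak_on_ramp_keeps_its_area(self):
        area = 12.0
        y = 0.4 * T / T[-1] + 0.2 + gaussian(T, 17.5, 0.3, area)
        out = correct_baseline(make_trace(T, y))
        got = np.trapezoid(out.absorbance, out.time)
        assert got == pytest.approx(area, rel=1e-3)

    def test_short_trace_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValidationError):
            correct_baseline(make_trace(t, np.zeros_like(t)), fit_fraction=0.01)


class TestDetectPeaks:
    def test_single_gaussian_area(self):
        chrom = make_trace(T, gaussian(T, 20.0, 0.3, 7.0))
        peaks = detect_peaks(chrom)
        assert len(peaks) == 1
        assert peaks["area"].iloc[0] == pytest.approx(7.0, rel=1e-3)

    def test_two_peaks_area_ratio(self):
        y = gaussian(T, 15.0, 0.3, 8.0) + gaussian(T, 22.0, 0.3, 4.0)
        peaks = detect_peaks(make_trace(T, y))
        assert len(peaks) == 2
        ratio = peaks["area"].iloc[0] / peaks["area"].iloc[1]
        assert ratio == pytest.approx(2.0, rel=5e-3)

    def test_noise_only_trace_yields_no_peaks(self):
        rng = np.random.default_rng(0)
        chrom = make_trace(T, 0.05 * rng.standard_normal(T.size))
        peaks = detect_peaks(chrom, min_height=0.5, min_prominence=0.5)
        assert len(peaks) == 0

    def test_noise_estimate_ignores_peaks(self):
        rng = np.random.default_rng(1)
        y = gaussian(T, 20.0, 0.3, 10.0) + 0.05 * rng.standard_normal(T.size)
        assert estimate_noise_sd(y) == pytest.approx(0.05, rel=0.15)


class TestNormalization:
    def _table(self, apexes, areas):
        y = sum(gaussian(T, c, 0.25, a) for c, a in zip(apexes, areas))
        return detect_peaks(make_trace(T, y))

    def test_normalized_values(self):
        peaks = self._table([8.0, 10.0, 12.0], [1.0, 5.0, 1.0])
        out = normalize_retention(peaks)
        assert np.allclose(out["normalized_apex"], [0.8, 1.0, 1.2], atol=1e-3)

    def test_time_axis_scale_invariance(self):
        peaks = self._table([8.0, 10.0, 12.0], [1.0, 5.0, 1.0])
        y = sum(gaussian(T, c, 0.25, a) for c, a in zip([8.0, 10.0, 12.0], [1.0, 5.0, 1.0]))
        scaled = detect_peaks(make_trace(2.0 * T, y))
        a = normalize_retention(peaks)["normalized_apex"].to_numpy()
        b = normalize_retention(scaled)["normalized_apex"].to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_main_only_table(self):
        peaks = self._table([10.0], [5.0])
        out = normalize_retention(peaks)
        assert out["normalized_apex"].tolist() == [1.0]

    def test_empty_table_raises(self):
        import pandas as pd

        with pytest.raises(NoPeaksError):
            normalize_retention(pd.DataFrame(columns=cv.chromatography.PEAK_COLUMNS))

    def test_reference_pattern_overrides_abundance(self):
        """When an acidic peak dominates, the reference-standard pattern
        still identifies the true main peak."""
        # acidic peak at 0.93 x main retention carries most of the area
        y = gaussian(T, 0.93 * 20.0, 0.2, 10.0) + gaussian(T, 20.0, 0.2, 3.0)
        peaks = detect_peaks(make_trace(T, y))
        assert select_main_peak(peaks) == 0  # abundance rule picks the acidic one
        refs = [0.93, 1.0]
        assert select_main_peak(peaks, reference_positions=refs) == 1


class TestQuantifyDistribution:
    def test_single_main_peak(self, clean_cparams):
        rec = cv.standard_record(composition=(0.0, 100.0, 0.0))
        dist = cv.quantify_distribution(cv.synthesize_chromatogram(rec, clean_cparams))
        assert (dist.acidic_pct, dist.main_pct, dist.basic_pct) == (0.0, 100.0, 0.0)

    def test_reference_standard_composition(self, standard_chromatogram):
        dist = cv.quantify_distribution(standard_chromatogram)
        assert dist.acidic_pct == pytest.approx(16.2, abs=0.2)
        assert dist.main_pct == pytest.approx(59.2, abs=0.2)
        assert dist.basic_pct == pytest.approx(24.5, abs=0.2)

    def test_peak_outside_window_excluded(self):
        inside = gaussian(T, 20.0, 0.2, 10.0) + gaussian(T, 18.0, 0.2, 3.0)
        outside = gaussian(T, 26.5, 0.2, 5.0)  # normalized 1.325 > 1.23
        d_in = cv.quantify_distribution(make_trace(T, inside))
        d_both = cv.quantify_distribution(make_trace(T, inside + outside))
        assert d_both.total_area == pytest.approx(d_in.total_area, rel=1e-6)
        assert d_both.basic_pct == pytest.approx(d_in.basic_pct, abs=1e-6)

    def test_no_product_raises(self):
        with pytest.raises(NoPeaksError, match="no product"):
            cv.quantify_distribution(make_trace(T, np.zeros_like(T)), min_height=0.1)

    def test_absorbance_scale_invariance(self, standard_chromatogram):
        from dataclasses import replace

        d0 = cv.quantify_distribution(standard_chromatogram)
        scaled = replace(standard_chromatogram, absorbance=standard_chromatogram.absorbance * 7.3)
        d1 = cv.quantify_distribution(scaled)
        assert d1.acidic_pct == pytest.approx(d0.acidic_pct, abs=1e-9)
        assert d1.total_area == pytest.approx(7.3 * d0.total_area, rel=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.tuples(
        st.floats(2.0, 95.0), st.floats(2.0, 95.0), st.floats(2.0, 95.0)
    ).map(lambda t: tuple(100.0 * x / sum(t) for x in t))
)
def test_random_compositions_sum_and_roundtrip(composition):
    """Percentages sum to 100 exactly, and a noiseless trace of any
    valley-separated composition is recovered within 0.2 points."""
    cparams = cv.ChromatogramParams(
        noise_sd=0.0, retention_jitter_sd=0.0, baseline_drift=0.0, baseline_offset=0.0
    )
    rec = cv.standard_record(composition=composition)
    refs = sorted(cparams.peak_positions_normalized.values())
    dist = cv.quantify_distribution(
        cv.synthesize_chromatogram(rec, cparams), reference_positions=refs
    )
    assert dist.acidic_pct + dist.main_pct + dist.basic_pct == pytest.approx(100.0, abs=1e-9)
    assert dist.acidic_pct == pytest.approx(composition[0], abs=0.2)
    assert dist.main_pct == pytest.approx(composition[1], abs=0.2)
    assert dist.basic_pct == pytest.approx(composition[2], abs=0.2)


class TestCalibration:
    def test_zero_area_zero_mass(self):
        cal = cv.Calibration(slope=0.2, intercept=0.0)
        assert cv.estimate_titer_from_area(0.0, cal) == 0.0

    def test_identity_roundtrip(self):
        masses = np.linspace(10, 200, 20)
        areas = 0.2 * masses
        cal = cv.fit_area_calibration(areas, masses)
        assert cal.slope == pytest.approx(0.2, rel=1e-6)
        for m in (25.0, 110.0):
            assert cv.estimate_titer_from_area(0.2 * m, cal) == pytest.approx(m, rel=1e-6)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(CalibrationError):
            cv.Calibration(slope=-0.1)

    def test_slope_ci_coverage(self):
        """95% CI of the calibration slope covers the truth in >= 90%
        of simulated 46-sample calibrations."""
        rng = np.random.default_rng(7)
        m_true, sigma, n = 0.2, 1.5, 46
        masses = rng.uniform(20, 250, size=n)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            areas = m_true * masses + sigma * rng.standard_normal(n)
            cal = cv.fit_area_calibration(areas, masses)
            lo, hi = cal.slope_ci
            hits += lo <= m_true <= hi
        assert hits / n_sim >= 0.90


class TestConsistency:
    def _dist(self, a, m, b):
        total = a + m + b
        return cv.ChargeDistribution(
            acidic_pct=100 * a / total,
            main_pct=100 * m / total,
            basic_pct=100 * b / total,
            total_area=total,
            acidic_area=a,
            main_area=m,
            basic_area=b,
        )

    def test_identical_replicates_zero_cv(self):
        out = cv.distribution_consistency([self._dist(2, 6, 2)] * 5)
        assert np.allclose(out["cv_pct"], 0.0)

    def test_hand_computed_cv(self):
        # classes {10, 20}%: mean 15, sample sd 7.0711, CV 47.14%
        d1 = self._dist(10, 70, 20)
        d2 = self._dist(20, 70, 10)
        out = cv.distribution_consistency([d1, d2])
        assert out.loc["acidic", "mean_pct"] == pytest.approx(15.0)
        assert out.loc["acidic", "sd_pct"] == pytest.approx(7.0711, abs=1e-4)
        assert out.loc["acidic", "cv_pct"] == pytest.approx(47.1405, abs=1e-3)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            cv.distribution_consistency([self._dist(1, 2, 1)])
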