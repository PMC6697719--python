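"""D(t) accumulation and reaction-constant regression."""

import numpy as np
import pandas as pd
import pytest

import chargevar as cv
from chargevar.errors import ValidationError
from chargevar.kinetics import KineticDataset, compute_D, fit_by_temperature, fit_k, predict_acidic

from conftest import kinetic_datasets


def frames_from(days, glucose, delta_mab, acidic=None, temperature=37.0):
    """Minimal corrected/rates frames for direct compute_D input."""
    days = np.asarray(days, dtype=float)
    corrected = pd.DataFrame(
        {
            "day": days,
            "glucose": glucose,
            "temperature": temperature,
            "titer_acidic_corr": acidic if acidic is not None else np.zeros_like(days),
        }
    )
    rates = pd.DataFrame(
        {
            "midpoint_day": 0.5 * (days[:-1] + days[1:]),
            "dt": np.diff(days),
            "delta_mab": delta_mab,
        }
    )
    return rates, corrected


class TestComputeD:
    def test_zero_glucose_zero_D(self):
        rates, corrected = frames_from([0, 1, 2, 3], np.zeros(4), np.ones(3))
        ds = compute_D(rates, corrected)
        assert np.allclose(ds.D_values, 0.0)

    def test_constant_integrand_closed_form(self):
        r, g, T = 0.25, 3.0, 6
        rates, corrected = frames_from(
            np.arange(T + 1), np.full(T + 1, g), np.full(T, r)
        )
        ds = compute_D(rates, corrected)
        assert ds.D_values[-1] == pytest.approx(r * g * T, rel=1e-12)

    def test_matches_dense_riemann_oracle(self):
        """Trapezoid accumulation equals brute-force integration of the
        piecewise model (production constant per interval, glucose
        linear between samples) on 100 random trajectories."""
        rng = np.random.default_rng(42)
        step = 1e-3
        for _ in range(100):
            n = rng.integers(5, 15)
            days = np.arange(n + 1, dtype=float)
            glucose = rng.uniform(0.0, 15.0, n + 1)
            delta = rng.uniform(0.0, 0.3, n)
            rates, corrected = frames_from(days, glucose, delta)
            ds = compute_D(rates, corrected)
            tau = np.arange(0.0, n, step) + step / 2.0
            g_tau = np.interp(tau, days, glucose)
            d_tau = delta[np.floor(tau).astype(int)]
            oracle = np.sum(g_tau * d_tau) * step
            assert ds.D_values[-1] == pytest.approx(oracle, rel=1e-3)

    def test_misaligned_days_rejected(self):
        rates, corrected = frames_from([0, 1, 2], [1, 1, 1], [0.1, 0.1])
        rates["midpoint_day"] += 0.5
        with pytest.raises(ValidationError, match="misaligned"):
            compute_D(rates, corrected)

    def test_simulated_run_satisfies_rate_law_exactly(self, noiseless_study):
        """acidic(t) = k * D(t) holds to machine precision per run."""
        for run in noiseless_study:
            (ds,) = kinetic_datasets([run])
            k = run.params.k_per_temp[ds.temperature_group]
            assert np.allclose(ds.acidic_conc, k * ds.D_values, rtol=1e-9, atol=1e-15)


class TestFitK:
    def _dataset(self, k=0.09, n=10, sigma=0.0, rng=None, temp=37.0):
        D = np.linspace(0.0, 5.0, n)
        a = k * D
        if sigma and rng is not None:
            a = a + sigma * rng.standard_normal(n)
            a[0] = 0.0
        return KineticDataset(times=np.arange(n, dtype=float), D_values=D, acidic_conc=a, temperature_group=temp)

    def test_exact_noiseless_recovery(self):
        fit = fit_k([self._dataset(k=0.09)])
        assert fit.k == pytest.approx(0.09, rel=1e-12)
        assert fit.intercept_diagnostic == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_acidic_zero_slope(self):
        fit = fit_k([self._dataset(k=0.0)])
        assert fit.k == 0.0

    def test_slope_unbiased_under_noise(self):
        """Monte-Carlo: the through-origin estimator is unbiased."""
        rng = np.random.default_rng(3)
        ks = [fit_k([self._dataset(k=0.05, n=12, sigma=0.02, rng=rng)]).k for _ in range(200)]
        ks = np.array(ks)
        se = ks.std(ddof=1) / np.sqrt(ks.size)
        assert abs(ks.mean() - 0.05) < 2 * se

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValidationError):
            fit_k([self._dataset(temp=37.0), self._dataset(temp=31.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_k([self._dataset(n=2)])

    def test_zero_D_with_acidic_flagged(self):
        ds = KineticDataset(
            times=np.arange(4.0),
            D_values=np.zeros(4),
            acidic_conc=np.array([0.0, 0.1, 0.2, 0.3]),
            temperature_group=37.0,
        )
        fit = fit_k([ds])
        assert any("model violated" in f for f in fit.flags)


class TestFitByTemperature:
    def test_recovers_generating_constants(self, noiseless_study):
        fits = fit_by_temperature(kinetic_datasets(noiseless_study))
        for temp, fit in fits.items():
            assert fit.k == pytest.approx(cv.K_PER_TEMP[temp], rel=1e-9)

    def test_identical_constants_indistinguishable(self):
        same_k = {37.0: 0.05, 34.0: 0.05, 31.0: 0.05}
        runs = cv.generate_study(cv.study_design(master_seed=5, noisy=False, k_per_temp=same_k))
        fits = fit_by_temperature(kinetic_datasets(runs))
        ks = [f.k for f in fits.values()]
        assert max(ks) - min(ks) < 1e-9

    def test_single_group(self, noiseless_study):
        subset = [ds for ds in kinetic_datasets(noiseless_study) if ds.temperature_group == 37.0]
        fits = fit_by_temperature(subset)
        assert list(fits) == [37.0]

    def test_fitted_k_ordered_with_temperature(self, noiseless_study):
        fits = fit_by_temperature(kinetic_datasets(noiseless_study))
        assert fits[37.0].k > fits[34.0].k > fits[31.0].k


class TestPredict:
    def test_trivial_values(self):
        assert np.allclose(predict_acidic(0.0, [1.0, 2.0]), 0.0)
        assert np.allclose(predict_acidic(2.0, [0, 1, 2]), [0, 2, 4])

    def test_cross_replicate_prediction(self):
        """k fitted on replicate 0 predicts replicate 1 with residuals
        comparable to in-sample (both ~0 noiseless)."""
        runs = cv.generate_study(
            cv.study_design(master_seed=9, temperatures=(34.0,), feeds=(20.0,), noisy=False)
        )
        ds0, ds1 = kinetic_datasets(runs)
        fit = fit_k([ds0])
        resid = ds1.acidic_conc - predict_acidic(fit.k, ds1.D_values)
        assert np.sqrt(np.mean(resid**2)) <= max(2 * fit.residual_sd, 1e-10)
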