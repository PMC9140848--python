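"""Sweep bookkeeping, Δlog(Φ) algebra, and the quadratic peak fit."""

import numpy as np
import pandas as pd
import pytest

import phitau as pt


@pytest.fixture(scope="module")
def planted():
    wake, anesth = pt.two_condition_sweep(tau_star=10, seed=21)
    return wake, anesth


class TestSweepRecords:
    def test_one_record_per_unit_and_tau(self, small_nonlinear_runs):
        df = pt.sweep(small_nonlinear_runs, "skipping", tau_grid=(5, 10))
        assert len(df) == 2 * len(small_nonlinear_runs)
        assert df.duplicated(["subject", "pair", "run", "condition", "method", "tau"]).sum() == 0
        assert set(df["tau"]) == {5, 10}

    def test_tau_in_ms_uses_sampling_rate(self, small_nonlinear_runs):
        df = pt.sweep(
            small_nonlinear_runs[:1], "skipping", tau_grid=(10,), sampling_rate_hz=1000.0
        )
        assert df["tau_ms"].iloc[0] == 10.0

    def test_pairs_mode_enumerates_channel_pairs(self):
        runs = pt.simulate(pt.non_markovian_3ch(n_timepoints=1200, n_runs=1, seed=13))
        df = pt.sweep(runs, "skipping", tau_grid=(10,), channel_pairs="pairs")
        assert sorted(df["pair"]) == ["0-1", "0-2", "1-2"]

    def test_nonlinear_model_recovers_its_lag_both_methods(self, small_nonlinear_runs):
        grid = (1, 5, 8, 10, 13, 20, 64)
        for method in ("skipping", "downsampling"):
            df = pt.sweep(small_nonlinear_runs, method, tau_grid=grid)
            assert pt.argmax_tau(df) == 10, method


class TestDeltaLogPhi:
    def test_identical_inputs_give_zero(self, planted):
        wake, _ = planted
        delta = pt.delta_log_phi(wake, wake)
        np.testing.assert_allclose(delta["delta_log_phi"], 0.0, atol=1e-12)

    def test_constant_ratio_e_gives_delta_one(self, planted):
        wake, _ = planted
        scaled = wake.copy()
        scaled["log_phi"] = scaled["log_phi"] - 1.0
        delta = pt.delta_log_phi(wake, scaled)
        np.testing.assert_allclose(delta["delta_log_phi"], 1.0, atol=1e-12)

    def test_antisymmetry(self, planted):
        wake, anesth = planted
        d1 = pt.delta_log_phi(wake, anesth)
        d2 = pt.delta_log_phi(anesth, wake)
        np.testing.assert_allclose(
            d1["delta_log_phi"].to_numpy(), -d2["delta_log_phi"].to_numpy(), atol=1e-12
        )

    def test_unmatched_and_missing_records_are_excluded(self, planted):
        wake, anesth = planted
        wake = wake.copy()
        wake.loc[wake.index[0], "log_phi"] = np.nan  # zero Phi -> missing log
        anesth = anesth[anesth["tau"] != 512]  # unmatched tau
        delta = pt.delta_log_phi(wake, anesth)
        assert not delta["delta_log_phi"].isna().any()
        assert 512 not in set(delta["tau"])
        assert len(delta) == len(wake) - len(wake[wake["tau"] == 512]) - 1


class TestQuadraticPeakFit:
    def test_exact_parabola_is_interpolated(self):
        # single subject, noiseless: y = 2 - 0.5*(x-3)^2, apex at x=3 -> tau=8
        taus = np.array([1, 2, 4, 8, 16, 32, 64])
        x = np.log2(taus)
        df = pd.DataFrame(
            {
                "subject": "s0",
                "pair": "p0",
                "tau": taus,
                "delta_log_phi": 2.0 - 0.5 * (x - 3.0) ** 2,
            }
        )
        fit = pt.fit_quadratic_peak(df)
        assert fit.beta2 == pytest.approx(-0.5, abs=1e-8)
        assert fit.beta1 == pytest.approx(3.0, abs=1e-8)
        assert fit.beta0 == pytest.approx(2.0 - 4.5, abs=1e-8)
        assert fit.turning_point_tau == pytest.approx(8.0, abs=1e-6)
        assert fit.is_local_max
        assert "single subject" in fit.notes[0]

    def test_planted_bump_recovered_with_significant_quadratic(self, planted):
        wake, anesth = planted
        fit = pt.fit_quadratic_peak(pt.delta_log_phi(wake, anesth))
        assert fit.is_local_max
        assert 8 < fit.turning_point_tau < 13  # within one grid step of 10
        assert fit.chi2 > 50
        assert fit.p_value < 1e-10
        assert fit.df == 1
        assert set(fit.random_effect_variances) >= {"subject", "residual"}

    def test_upward_parabola_is_classified_local_min(self):
        taus = np.array([1, 2, 4, 8, 16])
        x = np.log2(taus)
        df = pd.DataFrame(
            {"subject": "s0", "pair": "p0", "tau": taus, "delta_log_phi": (x - 2) ** 2}
        )
        fit = pt.fit_quadratic_peak(df)
        assert not fit.is_local_max
        assert fit.turning_point_tau == pytest.approx(4.0, abs=1e-6)

    def test_too_few_taus_raises(self):
        df = pd.DataFrame(
            {"subject": "s0", "pair": "p0", "tau": [1, 2], "delta_log_phi": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="3 distinct tau"):
            pt.fit_quadratic_peak(df)


class TestTurningPoint:
    def test_closed_form(self):
        tau, is_max = pt.turning_point(beta1=np.log2(10) * 2 * 0.01, beta2=-0.01)
        assert tau == pytest.approx(10.0, rel=1e-12)
        assert is_max

    def test_zero_curvature_raises(self):
        with pytest.raises(ValueError):
            pt.turning_point(0.1, 0.0)

    def test_intermediate_peak_criterion(self):
        fit = pt.PeakFit(
            beta0=0.0, beta1=0.2, beta2=-0.02, chi2=10.0, df=1, p_value=0.001,
            turning_point_tau=32.0, is_local_max=True,
        )
        assert pt.is_intermediate_peak(fit, pt.DEFAULT_TAU_GRID)
        fit_edge = pt.PeakFit(
            beta0=0.0, beta1=0.2, beta2=-0.02, chi2=10.0, df=1, p_value=0.001,
            turning_point_tau=0.5, is_local_max=True,
        )
        assert not pt.is_intermediate_peak(fit_edge, pt.DEFAULT_TAU_GRID)
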