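"""Dose-response fitting and benchmark-dose estimation."""

import numpy as np
import pytest

from toxmix import compute_bmd, exclude_nonmonotonic_top, fit_candidates, fit_linear
from toxmix.drmodels import DegenerateDesignError, LinearDRFit, linear_curvefit

RNG = np.random.default_rng(99)


def line_data(a=0.05, b=-1e-5, doses=(0, 0, 10, 10, 100, 100, 1000, 1000),
              noise=0.0, rng=None):
    d = np.asarray(doses, dtype=float)
    y = a + b * d
    if noise:
        y = y + (rng or RNG).normal(0, noise, size=d.size)
    return d, y


class TestFitLinear:
    def test_exact_interpolation_of_noise_free_line(self):
        d, y = line_data()
        fit = fit_linear(d, y)
        assert fit.a == pytest.approx(0.05, abs=1e-12)
        assert fit.b == pytest.approx(-1e-5, abs=1e-12)
        assert fit.R0 == pytest.approx(0.05, abs=1e-12)

    def test_constant_responses_give_zero_slope(self):
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        fit = fit_linear(d, np.full(6, 0.7))
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.a == pytest.approx(0.7, abs=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_estimates_inside_oracle_confidence_intervals(self, linear_study):
        """Seeded synthetic study: (a, b) inside closed-form OLS 95% CIs."""
        from scipy import stats
        design, truth, doses, responses = linear_study
        fit = fit_linear(doses, responses)
        t_sba = truth.endpoints["SBA"]
        d = doses
        sxx = np.sum((d - d.mean()) ** 2)
        se_b = fit.residual_sd / np.sqrt(sxx)
        se_a = fit.residual_sd * np.sqrt(1 / d.size + d.mean() ** 2 / sxx)
        tcrit = stats.t.ppf(0.975, d.size - 2)
        assert abs(fit.b - t_sba.slope) < tcrit * se_b
        assert abs(fit.a - t_sba.intercept) < tcrit * se_a


class TestFitCandidates:
    def test_nested_models_agree_on_linear_data(self):
        d, y = line_data(doses=np.repeat([0, 1, 5, 25, 100], 20), noise=0.002,
                         rng=np.random.default_rng(1))
        fits = {f.name: f for f in fit_candidates(d, y, ["linear", "power",
                                                         "polynomial2"])}
        aics = [fits[m].aic for m in ("linear", "power", "polynomial2")]
        assert max(aics) - min(aics) <= 2.01

    def test_hill_preferred_for_sharp_low_dose_drop(self):
        rng = np.random.default_rng(2)
        d = np.repeat([0.0, 0.76, 3.2, 50.0, 2066.0], 60)
        mu = 0.064 - 0.02 * d / (0.5 + d)  # saturating drop below 1 ug/L
        y = mu + rng.normal(0, 0.005, d.size)
        fits = {f.name: f for f in fit_candidates(d, y, ["linear", "hill"])}
        assert fits["hill"].converged
        assert fits["hill"].aic < fits["linear"].aic

    def test_single_model_request(self):
        d, y = line_data()
        fits = fit_candidates(d, y, ["linear"])
        assert len(fits) == 1 and fits[0].name == "linear"

    def test_list_sorted_by_aic_and_failures_flagged(self):
        d, y = line_data(noise=0.001, rng=np.random.default_rng(3))
        fits = fit_candidates(d, y)  # only 4 dose levels: hill/exp3 need >= 4
        aics = [f.aic for f in fits if np.isfinite(f.aic)]
        assert aics == sorted(aics)
        # insufficient dose levels for hill with 3 distinct doses
        d3 = np.repeat([0.0, 1.0, 10.0], 5)
        y3 = 0.05 - 1e-3 * d3
        res = {f.name: f for f in fit_candidates(d3, y3, ["linear", "hill"])}
        assert not res["hill"].converged
        assert "dose levels" in res["hill"].message

    def test_unknown_model_rejected(self):
        d, y = line_data()
        with pytest.raises(ValueError, match="unknown model"):
            fit_candidates(d, y, ["linear", "probit"])

    def test_aic_ordering_invariant_under_dose_rescaling(self):
        rng = np.random.default_rng(4)
        d = np.repeat([0.0, 0.76, 3.2, 50.0, 2066.0], 40)
        y = 0.06 - 1.2e-5 * d + rng.normal(0, 0.004, d.size)
        order = [f.name for f in fit_candidates(d, y, ["linear", "polynomial2",
                                                       "power"])]
        order_uM = [f.name for f in fit_candidates(d / 500.13, y,
                                                   ["linear", "polynomial2",
                                                    "power"])]
        assert order == order_uM
        # closed-form members have exactly invariant AIC
        aic = {f.name: f.aic for f in fit_candidates(d, y, ["linear", "polynomial2"])}
        aic_uM = {f.name: f.aic for f in fit_candidates(d / 500.13, y,
                                                        ["linear", "polynomial2"])}
        for m in aic:
            assert aic[m] == pytest.approx(aic_uM[m], rel=1e-9)


class TestComputeBMD:
    def test_linear_closed_form(self):
        fit = LinearDRFit.from_params(a=0.05, b=-1e-3, R0=0.05)
        res = compute_bmd(fit, control_mean=0.05, control_sd=0.01, bmr_sd=1.0)
        assert res.bmd == pytest.approx(10.0, rel=1e-9)

    def test_bmdl_below_bmd_and_converging_with_vanishing_noise(self, linear_study):
        design, truth, doses, responses = linear_study
        fit = fit_linear(doses, responses)
        res = compute_bmd(fit, fit.R0, fit.control_sd)
        assert res.status == "ok"
        assert 0 < res.bmdl < res.bmd
        assert res.bmdl_method == "profile"
        # deterministic responses: BMDL -> BMD
        exact = fit.predict(doses) + np.random.default_rng(0).normal(0, 1e-9, doses.size)
        fit0 = fit_linear(doses, exact)
        res0 = compute_bmd(fit0, fit.R0, fit.control_sd)
        assert res0.bmdl == pytest.approx(res0.bmd, rel=1e-3)

    def test_profile_bmdl_matches_bootstrap_oracle(self, linear_study):
        """Profile bound vs a stratified case-resampling bootstrap (2000
        draws, 5th percentile of the closed-form BMD) within 10%."""
        design, truth, doses, responses = linear_study
        fit = fit_linear(doses, responses)
        shift = fit.control_sd  # bmr_sd = 1
        res = compute_bmd(fit, fit.R0, fit.control_sd)
        rng = np.random.default_rng(2024)
        levels = np.unique(doses)
        idx_by_level = [np.nonzero(doses == lv)[0] for lv in levels]
        boot = np.empty(2000)
        for i in range(2000):
            take = np.concatenate([rng.choice(ix, size=ix.size, replace=True)
                                   for ix in idx_by_level])
            d_b, y_b = doses[take], responses[take]
            b_b = (np.sum((d_b - d_b.mean()) * (y_b - y_b.mean()))
                   / np.sum((d_b - d_b.mean()) ** 2))
            boot[i] = shift / abs(b_b)
        bmdl_boot = np.quantile(boot, 0.05)
        assert res.bmdl == pytest.approx(bmdl_boot, rel=0.10)

    def test_nonlinear_bmd_and_profile(self, linear_study):
        design, truth, doses, responses = linear_study
        fits = {f.name: f for f in fit_candidates(doses, responses,
                                                  ["linear", "power"])}
        lin = compute_bmd(fits["linear"], 0.0456, 0.013)
        pw = compute_bmd(fits["power"], 0.0456, 0.013)
        assert pw.status == "ok"
        assert pw.bmd == pytest.approx(lin.bmd, rel=0.15)
        assert 0 < pw.bmdl <= pw.bmd

    def test_no_solution_when_bmr_unreachable(self):
        d = np.repeat([0.0, 1.0, 10.0, 100.0], 5)
        y = 0.05 - 1e-9 * d  # essentially flat
        fit = fit_linear(d, y)
        res = compute_bmd(fit, 0.05, 0.01)
        assert res.status == "no_solution"
        assert np.isnan(res.bmd)

    def test_extrapolation_below_lowest_dose_flagged(self):
        rng = np.random.default_rng(5)
        d = np.repeat([0.0, 0.76, 3.2, 50.0, 2066.0], 60)
        mu = 0.064 - 0.02 * d / (0.05 + d)  # drop far below the lowest dose
        y = mu + rng.normal(0, 0.003, d.size)
        fits = fit_candidates(d, y, ["hill"])
        res = compute_bmd(fits[0], 0.064, 0.013)
        assert res.status == "ok"
        assert res.bmd < 0.76 / 3
        assert res.qc_flag == "questionable_extrapolation"

    def test_invalid_inputs_rejected(self):
        fit = LinearDRFit.from_params(0.05, -1e-3, 0.05)
        with pytest.raises(ValueError, match="control_sd"):
            compute_bmd(fit, 0.05, -1.0)
        with pytest.raises(ValueError, match="direction"):
            compute_bmd(fit, 0.05, 0.01, direction="sideways")


class TestExcludeNonmonotonicTop:
    def test_reversing_top_group_dropped(self):
        means = [0.064, 0.063, 0.063, 0.062, 0.046, 0.075]
        retained, dropped = exclude_nonmonotonic_top(means, control_sd=0.013)
        assert dropped and retained == [0, 1, 2, 3, 4]

    def test_monotone_series_kept(self):
        retained, dropped = exclude_nonmonotonic_top(
            [0.064, 0.060, 0.055, 0.050, 0.040, 0.030], control_sd=0.013)
        assert not dropped and retained == [0, 1, 2, 3, 4, 5]

    def test_small_reversal_within_one_sd_kept(self):
        retained, dropped = exclude_nonmonotonic_top(
            [0.064, 0.060, 0.050, 0.040, 0.030, 0.035], control_sd=0.013)
        assert not dropped

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="3 dose groups"):
            exclude_nonmonotonic_top([0.06, 0.05], control_sd=0.01)
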