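import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize_scalar

import redfac as rf
from redfac.regression import natural_cubic_basis
from tests.conftest import simulate_study


def brute_force_fg_beta(data, x):
    """Independent maximiser of the weighted Fine-Gray partial likelihood
    (golden-section on the 1-d negative log PL, no Newton machinery)."""
    w = rf.ipcw_weights(data)
    times = w.event_times
    W = w.weights
    comp = data.status == 2
    risk = (data.time[:, None] >= times[None, :]) | comp[:, None]
    ev = np.array([int(np.flatnonzero(data.time == t)[0]) for t in times])

    def neg_pl(beta):
        ll = 0.0
        for j in range(len(times)):
            denom = np.sum(risk[:, j] * W[:, j] * np.exp(beta * x))
            ll += beta * x[ev[j]] - np.log(denom)
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-4, 4), method="bounded",
                          options={"xatol": 1e-12})
    return res.x


class TestCauseSpecificCox:
    def test_matches_lifelines_without_competing_events(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        z = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x - 0.3 * z))
        c = rng.uniform(0, 2, n)
        df = pd.DataFrame({"time": np.minimum(t, c),
                           "status": (t <= c).astype(int), "x": x, "z": z})
        d = rf.CompetingRisksData(df)
        res = rf.CauseSpecificCox(d, ["x", "z"]).fit()
        oracle = CoxPHFitter().fit(df, "time", "status")
        np.testing.assert_allclose(res.params.to_numpy(),
                                   oracle.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.bse.to_numpy(),
                                   oracle.standard_errors_.to_numpy(), atol=1e-5)
        assert res.converged and not res.monotone

    def test_constant_offset_leaves_coefficients_unchanged(self, censored_study):
        plain = rf.CauseSpecificCox(censored_study, ["x"]).fit()
        shifted = rf.CauseSpecificCox(censored_study, ["x"],
                                      offset=rf.OffsetModel.constant(3.7)).fit()
        np.testing.assert_allclose(plain.params.to_numpy(),
                                   shifted.params.to_numpy(), atol=1e-12)
        # the baseline absorbs the shift
        ratio = shifted.baseline.increments / plain.baseline.increments
        np.testing.assert_allclose(ratio, np.exp(-3.7), rtol=1e-10)

    def test_monotone_likelihood_flagged(self):
        d = rf.CompetingRisksData(pd.DataFrame(
            {"time": [1.0, 2.0], "status": [1, 1], "x": [1.0, 0.0]}))
        with pytest.warns(UserWarning, match="monotone"):
            res = rf.CauseSpecificCox(d, ["x"]).fit()
        assert res.monotone and not res.converged

    def test_newton_matches_brute_force_maximum(self, censored_study):
        res = rf.FineGrayModel(censored_study, ["x"]).fit()
        beta_bf = brute_force_fg_beta(censored_study,
                                      censored_study.covariates("x")[:, 0])
        assert abs(res.params["x"] - beta_bf) <= 1e-6

    def test_summary_table(self, censored_study):
        tab = rf.CauseSpecificCox(censored_study, ["x"]).fit().summary()
        assert list(tab.columns[:2]) == ["coef", "se(coef)"]
        assert tab.attrs["converged"]


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.4 * x))
        c = rng.uniform(0, 2, n)
        d = rf.CompetingRisksData(pd.DataFrame(
            {"time": np.minimum(t, c), "status": (t <= c).astype(int), "x": x}))
        fg = rf.FineGrayModel(d, ["x"]).fit()
        csh = rf.CauseSpecificCox(d, ["x"]).fit()
        assert abs(fg.params["x"] - csh.params["x"]) <= 1e-9

    @pytest.mark.parametrize("censoring", [("admin", 0.6), ("uniform+admin", 1.8, 0.6)])
    def test_offset_route_equivalence(self, middle_middle, censoring):
        """Saturated-offset fit equals the Fine-Gray maximiser exactly,
        with and without random censoring before the horizon."""
        for seed in (0, 1, 2):
            d = simulate_study(middle_middle, n=300, seed=seed, censoring=censoring)
            gap = rf.equivalence_report(d, "x")
            assert gap <= 1e-6

    def test_equivalence_refuses_continuous_covariate(self, middle_middle):
        d = simulate_study(middle_middle, n=200, seed=4)
        frame = d.frame.copy()
        frame["cont"] = np.random.default_rng(0).normal(size=d.n)
        with pytest.raises(ValueError, match="continuous"):
            rf.equivalence_report(rf.CompetingRisksData(frame), "cont")

    def test_offset_with_unit_reduction_equals_cause_specific(self, censored_study):
        sat = rf.ReductionFactorEstimate(
            event_times=censored_study.event_times(1),
            levels=["overall"],
            values=pd.DataFrame(
                {"overall": np.ones(len(censored_study.event_times(1)))},
                index=censored_study.event_times(1)),
        )
        res = rf.fit_fine_gray_via_offset(censored_study, ["x"], sat)
        csh = rf.CauseSpecificCox(censored_study, ["x"]).fit()
        assert abs(res.params["x"] - csh.params["x"]) <= 1e-12

    def test_parameter_recovery_single_fit(self, middle_middle):
        d = simulate_study(middle_middle, n=2000, seed=77,
                           censoring=("uniform", 1.1))
        res = rf.CauseSpecificCox(d, ["x"]).fit()
        assert abs(res.params["x"] - 0.5) < 3 * res.bse["x"]


class TestReductionFactorGLM:
    def test_saturated_poisson_reproduces_ratio_estimates(self, censored_study):
        """Per-time log-link fit over a binary covariate is saturated: the
        fitted values equal the per-level weighted ratio estimates."""
        w = rf.ipcw_weights(censored_study)
        sat = rf.reduction_factor_np(censored_study, by="x", weights=w)
        glm = rf.ReductionFactorGLM(censored_study, ["x"], weights=w).fit()
        X = np.array([[0.0], [1.0]])
        pred = glm.predict_r(w.event_times, X)
        np.testing.assert_allclose(pred[0], np.minimum(sat.values[0.0], 1.0),
                                   atol=1e-7)
        np.testing.assert_allclose(pred[1], np.minimum(sat.values[1.0], 1.0),
                                   atol=1e-7)

    def test_per_time_coefficient_is_log_ratio(self, censored_study):
        w = rf.ipcw_weights(censored_study)
        sat = rf.reduction_factor_np(censored_study, by="x", weights=w)
        glm = rf.ReductionFactorGLM(censored_study, ["x"], weights=w).fit()
        expected = np.log(sat.values[1.0].to_numpy()
                          / sat.values[0.0].to_numpy())
        got = glm.per_time_coefficients["x"].to_numpy()
        ok = np.isfinite(expected)
        np.testing.assert_allclose(got[ok], expected[ok], atol=1e-6)

    def test_first_time_all_event_free_gives_unit_r(self, toy):
        w = rf.ipcw_weights(toy)
        glm = rf.ReductionFactorGLM(toy, ["x"], weights=w).fit()
        first = glm.per_time_coefficients.iloc[0]
        assert first["const"] == 0.0 and first["x"] == 0.0

    def test_pooled_spline_tracks_per_time_baseline(self, middle_middle):
        d = simulate_study(middle_middle, n=800, seed=21,
                           censoring=("uniform+admin", 1.8, 0.6))
        w = rf.ipcw_weights(d)
        per = rf.ReductionFactorGLM(d, ["x"], weights=w).fit()
        pooled = rf.ReductionFactorGLM(d, ["x"], weights=w,
                                       structure="pooled").fit()
        X = np.array([[0.0]])
        t_mid = np.quantile(w.event_times, [0.3, 0.5, 0.7])
        a = per.predict_r(t_mid, X)[0]
        b = pooled.predict_r(t_mid, X)[0]
        np.testing.assert_allclose(a, b, atol=0.08)

    def test_rejects_bad_options(self, toy):
        with pytest.raises(ValueError):
            rf.ReductionFactorGLM(toy, ["x"], link="probit")
        with pytest.raises(ValueError):
            rf.ReductionFactorGLM(toy, ["x"], family="poisson", link="logit")


class TestCoefficientRelation:
    def test_per_time_log_ratio_tracks_implied_coefficient(self, middle_middle):
        """The saturated per-time log-link coefficient γ(t*) = log r̂(t*|1) −
        log r̂(t*|0) tracks the model-implied β_FG(t) − β_CS on the central
        event times at large n."""
        d = rf.simulate_competing_risks(rf.SimulationDesign(
            n=20000, model=middle_middle, covariate_p=0.5,
            censoring=("admin", 1.5), seed=2))
        w = rf.ipcw_weights(d)
        sat = rf.reduction_factor_np(d, by="x", weights=w)
        tq = sat.event_times
        gamma_hat = np.log(sat.values[1.0].to_numpy()
                           / sat.values[0.0].to_numpy())
        grid = rf.default_grid(float(tq.max()) + 1e-9, 2001)
        gamma_th = np.interp(tq, grid, rf.beta_fg_curve(middle_middle, grid)) \
            - middle_middle.beta1
        sel = (tq >= np.quantile(tq, 0.05)) & (tq <= np.quantile(tq, 0.95))
        assert np.abs(gamma_hat[sel] - gamma_th[sel]).max() <= 0.1


class TestNaturalCubicBasis:
    def test_linearity_beyond_boundary_knots(self):
        knots = [0.0, 1.0, 2.0, 3.0]
        x = np.linspace(3.5, 6.0, 50)
        B = natural_cubic_basis(x, knots)
        for col in B.T:
            second_diff = np.diff(col, 2)
            np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_dimension(self):
        B = natural_cubic_basis(np.linspace(0, 3, 20), [0.0, 1.0, 2.0, 3.0])
        assert B.shape == (20, 3)
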