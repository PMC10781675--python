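import numpy as np
import pandas as pd
import pytest

from treatpath import design as dz
from treatpath import rp
from treatpath.rp import exponential_fit, fit, fit_from_json, fit_to_json, hazard_ratios, select_df


def simulate_weibull_table(n, shape, rate, seed, loghr=0.0, censor=365.24):
    """One-transition dataset from H(t|x) = rate * t^shape * exp(loghr * x)."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(int)
    t = (rng.exponential(size=n) / (rate * np.exp(loghr * x))) ** (1.0 / shape)
    event = t <= censor
    return pd.DataFrame({
        "entry": 0.0, "exit": np.minimum(t, censor), "event": event.astype(int),
        "imd_quintile": np.where(x == 1, 5, 1),
    })


class TestFit:
    def test_weibull_shape_identified_by_one_df(self):
        """log H linear in log t with slope = the Weibull shape."""
        data = simulate_weibull_table(20_000, shape=1.5, rate=1e-4, seed=1)
        f = fit(data, df_baseline=1, covariates=())
        se_gamma1 = f.se()[1]
        assert abs(f.gamma[1] - 1.5) < 3 * se_gamma1
        assert f.converged and f.gradient_norm < 1e-5

    def test_null_covariate_estimates_zero(self):
        data = simulate_weibull_table(10_000, shape=1.0, rate=0.003, seed=2, loghr=0.0)
        f = fit(data, df_baseline=1, covariates=("imd_quintile",))
        b = dict(zip(f.beta_names, f.beta))["imd_quintile[5]"]
        se = dict(zip(f.beta_names, f.se()[f.gamma.size:]))["imd_quintile[5]"]
        assert abs(b) < 3 * se

    def test_true_hazard_ratio_recovered(self):
        data = simulate_weibull_table(20_000, shape=1.0, rate=0.004, seed=3, loghr=np.log(1.3))
        f = fit(data, df_baseline=1, covariates=("imd_quintile",))
        hr = hazard_ratios(f).set_index("term")
        est = hr.loc["imd_quintile[5]"]
        assert est.lo < 1.3 < est.hi
        assert abs(est.hr - 1.3) < 0.06

    def test_matches_independent_weibull_mle(self):
        """With df=1 and no truncation the model is exactly Weibull regression."""
        lifelines = pytest.importorskip("lifelines")
        data = simulate_weibull_table(5_000, shape=1.3, rate=5e-4, seed=4)
        f = fit(data, df_baseline=1, covariates=())
        wf = lifelines.WeibullFitter().fit(data["exit"], data["event"])
        # lifelines: H(t) = (t / lambda_) ** rho_  =>  gamma1 = rho_, gamma0 = -rho_ log lambda_
        assert abs(f.gamma[1] - wf.rho_) < 1e-4 * abs(wf.rho_)
        assert abs(f.gamma[0] - (-wf.rho_ * np.log(wf.lambda_))) < 1e-4 * abs(f.gamma[0])

    def test_zero_events_rejected(self):
        data = pd.DataFrame({"entry": [0.0], "exit": [10.0], "event": [0]})
        with pytest.raises(rp.FitError):
            fit(data, covariates=())

    def test_ci_width_shrinks_like_root_n(self):
        widths = []
        for n in (2_000, 8_000, 32_000):
            data = simulate_weibull_table(n, shape=1.0, rate=0.004, seed=5, loghr=np.log(1.3))
            f = fit(data, df_baseline=1, covariates=("imd_quintile",))
            hr = hazard_ratios(f).set_index("term").loc["imd_quintile[5]"]
            widths.append(np.log(hr.hi) - np.log(hr.lo))
        np.testing.assert_allclose(widths[0] / widths[1], 2.0, rtol=0.25)
        np.testing.assert_allclose(widths[1] / widths[2], 2.0, rtol=0.25)


class TestPrediction:
    def test_exponential_closed_form(self):
        f = exponential_fit(0.004)
        t = np.linspace(1.0, 365.0, 50)
        np.testing.assert_allclose(
            rp.predict_cumhaz(f, dz.reference_profile(), t), 0.004 * t, rtol=1e-8)
        np.testing.assert_allclose(
            rp.predict_hazard(f, dz.reference_profile(), t), 0.004, rtol=1e-8)

    def test_cumhaz_monotone_on_accepted_fit(self, stage4_datasets):
        f = fit(stage4_datasets["h1"], df_baseline=3)
        t = np.linspace(0.5, 365.24, 1000)
        H = rp.predict_cumhaz(f, dz.reference_profile(), t)
        assert f.valid_hazard
        assert np.all(np.diff(H) >= 0)

    def test_survival_matches_kaplan_meier_at_deciles(self):
        lifelines = pytest.importorskip("lifelines")
        data = simulate_weibull_table(5_000, shape=1.4, rate=2e-4, seed=6)
        f = fit(data, df_baseline=2, covariates=())
        km = lifelines.KaplanMeierFitter().fit(data["exit"], data["event"])
        ev = data.loc[data["event"] == 1, "exit"]
        qs = np.quantile(ev, np.linspace(0.1, 0.9, 9))
        S_fit = f.survival(dz.reference_profile(), qs)
        S_km = km.survival_function_at_times(qs).to_numpy()
        assert np.abs(S_fit - S_km).max() < 0.02

    def test_json_round_trip_preserves_predictions(self, tmp_path, stage4_datasets):
        f = fit(stage4_datasets["h2"], df_baseline=2)
        path = tmp_path / "fit.json"
        fit_to_json(f, path)
        g = fit_from_json(path)
        t = np.linspace(1, 360, 30)
        prof = dz.reference_profile(4)
        np.testing.assert_allclose(g.cumhaz(prof, t), f.cumhaz(prof, t), rtol=1e-12)
        np.testing.assert_allclose(g.vcov, f.vcov)


class TestSelection:
    def test_singleton_grid_returns_that_df(self, stage4_datasets):
        sel = select_df(stage4_datasets["h2"], dfs=(2,), covariates=("imd_quintile",))
        assert sel.chosen_df == 2

    def test_bic_penalty_identity(self, stage4_datasets):
        sel = select_df(stage4_datasets["h2"], dfs=(1, 2), covariates=("imd_quintile",))
        tbl = sel.table
        np.testing.assert_allclose(
            tbl["bic"] + 2 * tbl["loglik"], tbl["k"] * np.log(sel.fits[1].n_events))
        np.testing.assert_allclose(tbl["aic"] + 2 * tbl["loglik"], 2 * tbl["k"])

    def test_empty_grid_rejected(self, stage4_datasets):
        with pytest.raises(ValueError):
            select_df(stage4_datasets["h1"], dfs=())


class TestHazardRatios:
    def test_closed_form_wald_interval(self):
        f = exponential_fit(0.01, effects={"sex[women]": 0.0})
        f.vcov = np.diag([0.0, 0.0, 0.01])  # se(beta) = 0.1
        hr = hazard_ratios(f)
        row = hr.set_index("term").loc["sex[women]"]
        assert row.hr == pytest.approx(1.00, abs=1e-12)
        assert row.lo == pytest.approx(np.exp(-1.959963985 * 0.1), abs=1e-6)
        assert row.hi == pytest.approx(np.exp(+1.959963985 * 0.1), abs=1e-6)


class TestDelayedEntry:
    def test_left_truncated_likelihood_is_consistent(self):
        """Rows entering late must condition on survival to entry: estimates
        from a heavily truncated sample agree with the truth."""
        rng = np.random.default_rng(7)
        n = 40_000
        rate = 0.005
        entry = rng.uniform(5.0, 120.0, n)
        t = entry + rng.exponential(1.0 / rate, n)  # exploits memorylessness
        censor = 365.24
        data = pd.DataFrame({
            "entry": entry, "exit": np.minimum(t, censor),
            "event": (t <= censor).astype(int),
        })
        f = fit(data, df_baseline=1, covariates=())
        lnH365 = f.gamma[0] + f.gamma[1] * np.log(365.24)
        grad = np.array([1.0, np.log(365.24)])
        se = float(np.sqrt(grad @ f.vcov[:2, :2] @ grad))
        assert abs(lnH365 - np.log(rate * 365.24)) < 3 * se
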