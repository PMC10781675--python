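import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

import treatpath as tp
from treatpath import design as dz
from treatpath.simulate import (
    ConfigurationError,
    SimulationParams,
    microsimulate_occupancy,
    truth_occupancy,
)

from conftest import closed_form_constant, constant_params


def test_identical_params_give_byte_identical_cohorts():
    params = tp.colon_stage4_like(n_patients=500, seed=99)
    a = tp.simulate_cohort(params).to_csv(index=False)
    b = tp.simulate_cohort(tp.colon_stage4_like(n_patients=500, seed=99)).to_csv(index=False)
    assert a == b


def test_empty_cohort_keeps_full_schema():
    params = tp.colon_stage4_like(n_patients=0, seed=1)
    df = tp.simulate_cohort(params)
    assert len(df) == 0
    for col in ("id", "age", "sex", "imd_quintile", "route", "t_treat", "t_death", "t_censor"):
        assert col in df.columns


def test_marginals_match_within_monte_carlo_error():
    """With registry-like marginals the women share lands near 46.3%."""
    params = tp.colon_stage4_like(n_patients=70_000, seed=5)
    covs = tp.generate_covariates(params)
    p = 0.463
    se = np.sqrt(p * (1 - p) / len(covs))
    assert abs((covs["sex"] == "women").mean() - p) < 3 * se
    assert 18.0 <= covs["age"].min() and covs["age"].max() <= 99.0


def test_uniform_quintiles_pass_goodness_of_fit():
    params = tp.colon_stage4_like(n_patients=50_000, seed=6)
    params.marginals["imd_quintile"] = {q: 0.2 for q in range(1, 6)}
    covs = tp.generate_covariates(params)
    counts = covs["imd_quintile"].value_counts().sort_index().to_numpy()
    _, p = stats.chisquare(counts)
    assert p > 0.001


def test_invalid_probability_vector_names_the_field():
    with pytest.raises(ConfigurationError, match="imd_quintile"):
        p = tp.colon_stage4_like(n_patients=10, seed=1)
        SimulationParams(**{**p.to_dict(), "marginals": {**p.marginals, "imd_quintile": {1: 0.5, 2: 0.6}}})


def test_zero_hazards_censor_everyone():
    params = constant_params(0.0, 0.0, 0.0, n=200, seed=3)
    sim = tp.simulate_cohort(params)
    assert sim["t_treat"].isna().all()
    assert sim["t_death"].isna().all()
    np.testing.assert_array_equal(sim["t_censor"], 365.24)


def test_constant_hazard_exit_from_state_1_matches_closed_form():
    l1, l2 = 0.004, 0.002
    params = constant_params(l1, l2, 0.003, n=100_000, seed=4)
    sim = tp.simulate_cohort(params)
    t_exit = np.fmin(sim["t_treat"].to_numpy(), sim["t_death"].to_numpy())
    in_state1 = np.isnan(t_exit) | (t_exit > 180.0)
    p = np.exp(-(l1 + l2) * 180.0)
    se = np.sqrt(p * (1 - p) / len(sim))
    assert abs(in_state1.mean() - p) < 3 * se


def test_weibull_exit_survival_matches_analytic_at_deciles():
    """Kaplan-Meier of time to first exit from state 1 vs exp(-(H1+H2))."""
    lifelines = pytest.importorskip("lifelines")
    params = tp.SimulationParams(
        n_patients=50_000, seed=8,
        baseline={
            "h1": {"family": "weibull", "shape": 1.5, "rate": 0.0005},
            "h2": {"family": "constant", "rate": 0.002},
            "h3": {"family": "constant", "rate": 0.003},
        },
        same_day_fraction=0.0,
    )
    sim = tp.simulate_cohort(params)
    t_exit = np.fmin(sim["t_treat"].to_numpy(), sim["t_death"].to_numpy())
    observed = ~np.isnan(t_exit)
    t = np.where(observed, t_exit, 365.24)
    km = lifelines.KaplanMeierFitter().fit(t, observed)
    qs = np.quantile(t[observed], np.linspace(0.1, 0.9, 9))
    S_km = km.survival_function_at_times(qs).to_numpy()
    S_true = np.exp(-(0.0005 * qs**1.5 + 0.002 * qs))
    assert np.abs(S_km - S_true).max() < 0.01


def test_truth_curves_initial_condition_and_invariants():
    params = tp.colon_stage4_like(n_patients=1, seed=1)
    tr = truth_occupancy(params, dz.reference_profile(5))
    assert (tr.p11[0], tr.p12[0], tr.p13[0]) == (1.0, 0.0, 0.0)
    total = tr.p11 + tr.p12 + tr.p13
    np.testing.assert_allclose(total, 1.0, atol=1e-9)
    assert np.all(np.diff(tr.p11) <= 1e-12)
    assert np.all(np.diff(tr.p13) >= -1e-12)
    for p in (tr.p11, tr.p12, tr.p13):
        assert np.all((p >= -1e-12) & (p <= 1 + 1e-12))
    assert tr.l1 > 0 and tr.l2 > 0 and tr.l3 > 0


def test_truth_curves_match_closed_form_and_ode_solution():
    l1, l2, l3 = 0.004, 0.002, 0.003
    params = constant_params(l1, l2, l3, n=1, seed=1)
    grid = np.array([0.0, 90.0, 180.0, 365.24])
    tr = truth_occupancy(params, dz.reference_profile(), grid=grid)
    p11, p12, p13 = closed_form_constant(grid, l1, l2, l3)
    np.testing.assert_allclose(tr.p11, p11, atol=1e-9)
    np.testing.assert_allclose(tr.p12, p12, atol=1e-9)

    # independent check: Kolmogorov forward equations
    def rhs(t, p):
        return [-(l1 + l2) * p[0], l1 * p[0] - l3 * p[1], l2 * p[0] + l3 * p[1]]

    sol = solve_ivp(rhs, (0, 365.24), [1.0, 0.0, 0.0], t_eval=grid, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(tr.p12, sol.y[1], atol=1e-7)


def test_microsimulation_agrees_with_truth_curves():
    params = tp.colon_stage4_like(n_patients=1, seed=1)
    profile = dz.reference_profile(3)
    times = np.arange(1, 13) * 365.24 / 12
    n = 100_000
    emp = microsimulate_occupancy(params, profile, times, n_paths=n, seed=12)
    tr = truth_occupancy(params, profile, grid=np.concatenate([[0.0], times]))
    for state in ("p11", "p12", "p13"):
        p = getattr(tr, state)[1:]
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        assert np.all(np.abs(emp[state].to_numpy() - p) <= 3 * se + 1e-9), state


def test_null_covariate_is_independent_of_event_times():
    """With a zero log-HR everywhere, logrank p-values are uniform."""
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import logrank_test

    pvals = []
    for rep in range(20):
        params = constant_params(0.006, 0.003, 0.004, n=2_000, seed=100 + rep)
        sim = tp.simulate_cohort(params)
        t_exit = np.fmin(sim["t_treat"].to_numpy(), sim["t_death"].to_numpy())
        observed = ~np.isnan(t_exit)
        t = np.where(observed, t_exit, 365.24)
        women = sim["sex"] == "women"
        res = logrank_test(t[women], t[~women], observed[women], observed[~women])
        pvals.append(res.p_value)
    _, ks_p = stats.kstest(pvals, "uniform")
    assert ks_p > 0.01


def test_params_yaml_round_trip(tmp_path):
    params = tp.colon_stage4_like(n_patients=100, seed=2)
    path = tmp_path / "params.yaml"
    params.to_yaml(path)
    again = SimulationParams.from_yaml(path)
    assert tp.simulate_cohort(again).equals(tp.simulate_cohort(params))
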