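import numpy as np
import pandas as pd
import pytest

import treatpath as tp
from treatpath import prep
from treatpath.prep import (
    StateFlowSummary,
    apply_inclusion_filters,
    build_transition_datasets,
    jitter_same_day,
    read_transition_csv,
    summarize_state_flow,
    write_transition_csv,
)

from conftest import constant_params


def make_cohort(rows):
    base = {
        "id": 0, "age": 70.0, "sex": "men", "ethnicity": "White", "imd_quintile": 1,
        "hf": 0, "mi": 0, "diab": 0, "copd": 0, "route": "gp_referral",
        "site": "colon", "stage": "II", "t_treat": np.nan, "t_death": np.nan,
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(base, id=i)
        row.update(r)
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

class TestInclusionFilters:
    def test_age_rule_boundaries(self):
        cohort = make_cohort([{"age": 17.9}, {"age": 18.0}, {"age": 99.0}, {"age": 99.5}])
        kept, tally = apply_inclusion_filters(cohort)
        assert tally["age"] == 2
        assert set(kept["age"]) == {18.0, 99.0}

    def test_empty_input(self):
        kept, tally = apply_inclusion_filters(make_cohort([{}]).iloc[:0])
        assert len(kept) == 0
        assert all(v == 0 for v in tally.values())

    def test_each_rule_counted_once_in_order(self):
        """Hand-enumerated fixture: 12 rows, one violating each rule."""
        cohort = make_cohort([
            {},                                        # clean
            {"age": 16.0},                             # age
            {"age": 101.0},                            # age
            {"dco": 1},                                # death certificate only
            {"missing_diag_month": 1},                 # missing diagnosis month
            {"t_death": -3.0},                         # death before diagnosis
            {"t_treat": 50.0, "t_death": 20.0},        # treatment after death
            {"imd_quintile": np.nan},                  # complete-case: deprivation
            {"ethnicity": np.nan},                     # complete-case: ethnicity
            {"route": np.nan},                         # complete-case: route
            {"stage": "missing"},                      # NOT dropped: own stratum
            {"t_treat": 30.0, "t_death": 200.0},       # clean
        ])
        kept, tally = apply_inclusion_filters(cohort)
        assert tally == {
            "age": 2, "dco": 1, "missing_diag_month": 1,
            "improper_dates": 2, "incomplete_covariates": 3,
        }
        assert len(kept) == 12 - 9
        assert (kept["stage"] == "missing").sum() == 1

    def test_missing_schema_raises(self):
        with pytest.raises(prep.InputError, match="age"):
            apply_inclusion_filters(pd.DataFrame({"id": [1]}))


# ---------------------------------------------------------------------------
# same-day jitter
# ---------------------------------------------------------------------------

class TestJitter:
    def test_treatment_on_diagnosis_day_moves_into_partial_day(self):
        cohort = make_cohort([{"t_treat": 0.0}])
        out = jitter_same_day(cohort, seed=1)
        assert 0.1 <= out.loc[0, "t_treat"] <= 0.9

    def test_tie_free_cohort_is_unchanged(self):
        cohort = make_cohort([{"t_treat": 3.5, "t_death": 100.0}, {}])
        out = jitter_same_day(cohort, seed=1)
        pd.testing.assert_frame_equal(out, cohort)

    def test_death_on_treatment_day_stays_ordered(self):
        """10,000 seeded draws: jittered death in (5.0, 5.9] and after treatment."""
        n = 10_000
        cohort = make_cohort([{"t_treat": 5.0, "t_death": 5.0}] * n)
        out = jitter_same_day(cohort, seed=7)
        td, tt = out["t_death"].to_numpy(), out["t_treat"].to_numpy()
        assert np.all(tt == 5.0)
        assert np.all((td > 5.0) & (td <= 5.9))
        assert np.all(td > tt)

    def test_double_tie_keeps_ordering_and_support(self):
        n = 10_000
        cohort = make_cohort([{"t_treat": 0.0, "t_death": 0.0}] * n)
        out = jitter_same_day(cohort, seed=3)
        tt, td = out["t_treat"].to_numpy(), out["t_death"].to_numpy()
        assert np.all((tt >= 0.1) & (tt <= 0.9))
        assert np.all((td > tt) & (td <= 0.9))

    def test_untreated_death_on_diagnosis_day(self):
        out = jitter_same_day(make_cohort([{"t_death": 0.0}]), seed=2)
        assert 0.1 <= out.loc[0, "t_death"] <= 0.9
        assert np.isnan(out.loc[0, "t_treat"])

    def test_deterministic_and_indicator_preserving(self):
        params = tp.colon_stage4_like(n_patients=2_000, seed=31, same_day_fraction=0.3)
        cohort = tp.simulate_cohort(params)
        a = jitter_same_day(cohort, seed=5)
        b = jitter_same_day(cohort, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["t_treat"].isna() == cohort["t_treat"].isna()).all()
        assert (a["t_death"].isna() == cohort["t_death"].isna()).all()


# ---------------------------------------------------------------------------
# transition risk sets and state flow
# ---------------------------------------------------------------------------

class TestTransitionDatasets:
    def test_definitional_rows(self):
        cohort = make_cohort([
            {"t_treat": 30.0},                      # treated day 30, censored
            {"t_death": 20.0},                      # dead day 20, never treated
        ])
        ds = build_transition_datasets(cohort)
        h1, h2, h3 = ds["h1"], ds["h2"], ds["h3"]
        assert (h1.loc[0, ["entry", "exit", "event"]] == [0.0, 30.0, 1]).all()
        assert (h2.loc[0, ["entry", "exit", "event"]] == [0.0, 30.0, 0]).all()
        assert (h3.loc[0, ["entry", "exit", "event"]] == [30.0, 365.24, 0]).all()
        assert (h1.loc[1, ["entry", "exit", "event"]] == [0.0, 20.0, 0]).all()
        assert (h2.loc[1, ["entry", "exit", "event"]] == [0.0, 20.0, 1]).all()
        assert len(h3) == 1  # untreated patients contribute no h3 row

    def test_unjittered_tie_raises(self):
        cohort = make_cohort([{"t_treat": 0.0}])
        with pytest.raises(prep.ConsistencyError):
            build_transition_datasets(cohort)

    def test_event_counts_match_state_flow(self):
        params = tp.colon_stage4_like(n_patients=1_000, seed=17)
        cohort = jitter_same_day(tp.simulate_cohort(params), seed=1)
        ds = build_transition_datasets(cohort)
        flow = summarize_state_flow(cohort)
        assert int(ds["h1"]["event"].sum()) == flow.x
        assert int(ds["h2"]["event"].sum()) == flow.y
        assert int(ds["h3"]["event"].sum()) == flow.z
        assert len(ds["h3"]) == flow.N2

    def test_round_trip_reconstructs_pathways(self):
        params = tp.colon_stage4_like(n_patients=500, seed=23)
        cohort = jitter_same_day(tp.simulate_cohort(params), seed=9)
        ds = build_transition_datasets(cohort)
        h1 = ds["h1"].set_index("id")
        h3 = ds["h3"].set_index("id")
        t_treat = h1.loc[h1["event"] == 1, "exit"]
        t_death_after = h3.loc[h3["event"] == 1, "exit"]
        t_death_before = ds["h2"].set_index("id").query("event == 1")["exit"]
        orig = cohort.set_index("id")
        np.testing.assert_allclose(t_treat, orig.loc[t_treat.index, "t_treat"])
        np.testing.assert_allclose(t_death_after, orig.loc[t_death_after.index, "t_death"])
        np.testing.assert_allclose(t_death_before, orig.loc[t_death_before.index, "t_death"])


class TestStateFlow:
    def test_empty_cohort(self):
        flow = summarize_state_flow(make_cohort([{}]).iloc[:0])
        assert flow == StateFlowSummary(0, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_hand_built_fixture(self):
        cohort = make_cohort(
            [{"t_treat": 10.0}] * 3                                  # treated, alive
            + [{"t_treat": 10.0, "t_death": 50.0}] * 2               # treated, dead
            + [{"t_death": 5.0}]                                     # dead untreated
            + [{}] * 4                                               # censored untreated
        )
        flow = summarize_state_flow(cohort)
        assert flow == StateFlowSummary(N1=10, n1=4, x=5, y=1, N2=5, n2=3, z=2, N3=3, n3=3)

    def test_conservation_on_random_cohorts(self):
        for seed in range(5):
            params = tp.colon_stage4_like(n_patients=300, seed=seed)
            flow = summarize_state_flow(tp.simulate_cohort(params))
            # identities are also asserted in the constructor; restate the key ones
            assert flow.N1 == flow.n1 + flow.x + flow.y
            assert flow.N3 == flow.y + flow.z == flow.n3

    def test_pre_treatment_death_fraction_matches_closed_form(self):
        l1, l2, T = 0.004, 0.008, 365.24
        params = constant_params(l1, l2, 0.003, n=50_000, seed=40)
        flow = summarize_state_flow(tp.simulate_cohort(params))
        expected = l2 / (l1 + l2) * (1 - np.exp(-(l1 + l2) * T))
        se = np.sqrt(expected * (1 - expected) / flow.N1)
        assert abs(flow.y / flow.N1 - expected) < 3 * se


def test_long_format_round_trip(tmp_path):
    params = tp.colon_stage4_like(n_patients=200, seed=3)
    cohort = jitter_same_day(tp.simulate_cohort(params), seed=4)
    ds = build_transition_datasets(cohort)
    path = tmp_path / "transitions.csv"
    write_transition_csv(ds, path)
    back = read_transition_csv(path)
    for t in ("h1", "h2", "h3"):
        pd.testing.assert_frame_equal(
            ds[t].reset_index(drop=True), back[t][ds[t].columns], check_dtype=False)
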