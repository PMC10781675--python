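"""Cohort filters and transition risk sets for the illness-death model.

A cohort table (one row per patient, times in days since diagnosis) is
filtered to the analysis population, same-day transitions are broken by a
random partial day in [0.1, 0.9], and the cohort is expanded into the three
transition-specific risk sets:

    h1  diagnosis -> treatment   entry 0,        exit min(t_treat, t_end)
    h2  diagnosis -> death       entry 0,        exit min(t_treat, t_end)
    h3  treatment -> death       entry t_treat,  exit t_end   (treated only)

h3 keeps time since diagnosis as its clock with delayed entry at the
treatment time, so post-treatment follow-up is never credited to the
pre-treatment states (immortal-time handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ADMIN_CENSOR_DAYS = 365.24

TRANSITIONS = ("h1", "h2", "h3")

COVARIATE_COLUMNS = [
    "age", "sex", "ethnicity", "imd_quintile", "hf", "mi", "diab", "copd",
    "route", "site", "stage",
]

#: complete-case covariates: rows missing any of these are dropped
COMPLETE_CASE_COLUMNS = ("imd_quintile", "ethnicity", "route")


class InputError(ValueError):
    pass


class ConsistencyError(RuntimeError):
    pass


@dataclass(frozen=True)
class StateFlowSummary:
    """State/transition counts: N_k patients entering state k, n_k staying
    at the end of follow-up, and x / y / z the 1->2, 1->3 and 2->3 movers."""

    N1: int
    n1: int
    x: int
    y: int
    N2: int
    n2: int
    z: int
    N3: int
    n3: int

    def __post_init__(self):
        assert self.N1 == self.n1 + self.x + self.y
        assert self.N2 == self.x == self.n2 + self.z
        assert self.N3 == self.y + self.z == self.n3


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"cohort table is missing column(s): {missing}")


def follow_up_end(df: pd.DataFrame, admin_censor_days: float = ADMIN_CENSOR_DAYS) -> pd.Series:
    """t_end = min(t_death, administrative horizon)."""
    return df["t_death"].fillna(np.inf).clip(upper=admin_censor_days)


def apply_inclusion_filters(
    raw: pd.DataFrame,
    admin_censor_days: float = ADMIN_CENSOR_DAYS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion rules in order; return survivors and a tally.

    Rules, applied sequentially (each count is rows dropped at that step):
    ``age`` outside [18, 99]; ``dco`` death-certificate-only flag;
    ``missing_diag_month`` flag; ``improper_dates`` (death before diagnosis or
    treatment after death); ``incomplete_covariates`` (missing deprivation,
    ethnicity or route — the complete-case rule).  Missing *stage* is kept:
    those patients form their own analysis stratum.
    """
    _require_columns(raw, ["age", "t_treat", "t_death"])
    df = raw.copy()
    tally: dict[str, int] = {}

    keep = df["age"].between(18.0, 99.0) & df["age"].notna()
    tally["age"] = int((~keep).sum())
    df = df[keep]

    for flag in ("dco", "missing_diag_month"):
        if flag in df.columns:
            drop = df[flag].fillna(0).astype(bool)
        else:
            drop = pd.Series(False, index=df.index)
        tally[flag] = int(drop.sum())
        df = df[~drop]

    t_end = follow_up_end(df, admin_censor_days)
    improper = (df["t_death"] < 0) | (df["t_treat"] < 0) | (df["t_treat"] > t_end + 1e-9)
    improper = improper.fillna(False)
    tally["improper_dates"] = int(improper.sum())
    df = df[~improper]

    incomplete = pd.Series(False, index=df.index)
    for c in COMPLETE_CASE_COLUMNS:
        if c in df.columns:
            col = df[c]
            incomplete |= col.isna() | (col.astype(str).str.strip() == "")
    tally["incomplete_covariates"] = int(incomplete.sum())
    df = df[~incomplete]

    return df.reset_index(drop=True), tally


def jitter_same_day(
    cohort: pd.DataFrame,
    seed: int,
    low: float = 0.1,
    high: float = 0.9,
    admin_censor_days: float = ADMIN_CENSOR_DAYS,
) -> pd.DataFrame:
    """Break same-day transitions by adding a random partial day.

    Any transition time equal to the previous state's entry time (treatment on
    the diagnosis day, death on the treatment day, or pre-treatment death on
    the diagnosis day) gets an independent uniform draw on [low, high] added.
    When both the treatment and death of one patient are jittered, the death
    draw is repeated until the ordering t_treat < t_death holds, keeping the
    stated support.  Tie-free cohorts are returned unchanged (same object
    content, copied).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    t_treat = df["t_treat"].to_numpy(dtype=float).copy()
    t_death = df["t_death"].to_numpy(dtype=float).copy()

    treated = ~np.isnan(t_treat)
    dead = ~np.isnan(t_death)

    tie_treat = treated & (t_treat == 0.0)
    tie_death = dead & np.where(treated, t_death == t_treat, t_death == 0.0)
    both = tie_treat & tie_death
    base_t, base_d = t_treat.copy(), t_death.copy()

    if tie_treat.any():
        t_treat[tie_treat] += rng.uniform(low, high, int(tie_treat.sum()))
    if tie_death.any():
        t_death[tie_death] += rng.uniform(low, high, int(tie_death.sum()))

    # re-draw (not clip) until the pathway ordering holds; for rows where both
    # times were jittered from the same day, both draws are repeated together
    # (success probability 1/2 per attempt), keeping the stated support
    for _ in range(10_000):
        bad = treated & dead & (t_death <= t_treat)
        if not bad.any():
            break
        b2 = bad & both
        if b2.any():
            t_treat[b2] = base_t[b2] + rng.uniform(low, high, int(b2.sum()))
            t_death[b2] = base_d[b2] + rng.uniform(low, high, int(b2.sum()))
        b1 = bad & ~both & tie_death
        if b1.any():
            t_death[b1] = base_d[b1] + rng.uniform(low, high, int(b1.sum()))
        b0 = bad & ~both & ~tie_death & tie_treat
        if b0.any():  # treatment jittered past an un-jittered death time
            t_treat[b0] = base_t[b0] + rng.uniform(low, high, int(b0.sum()))
    else:  # pragma: no cover - infeasible only if a death is recorded < 0.1 day
        raise ConsistencyError("could not restore t_treat < t_death by re-drawing")

    df["t_treat"] = t_treat
    df["t_death"] = t_death
    return df


def build_transition_datasets(
    cohort: pd.DataFrame,
    admin_censor_days: float = ADMIN_CENSOR_DAYS,
    covariate_columns: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Expand a filtered, jittered cohort into the three risk sets.

    Returns ``{"h1": ..., "h2": ..., "h3": ...}``, each with columns
    id, entry, exit, event plus the covariates present in the cohort.
    """
    _require_columns(cohort, ["id", "t_treat", "t_death"])
    if covariate_columns is None:
        covariate_columns = [c for c in COVARIATE_COLUMNS if c in cohort.columns]

    t_treat = cohort["t_treat"].to_numpy(dtype=float)
    t_death = cohort["t_death"].to_numpy(dtype=float)
    t_end = follow_up_end(cohort, admin_censor_days).to_numpy(dtype=float)

    treated = ~np.isnan(t_treat) & (t_treat <= t_end)
    died = ~np.isnan(t_death) & (t_death <= admin_censor_days)
    exit1 = np.where(treated, t_treat, t_end)

    covs = cohort[covariate_columns].reset_index(drop=True)

    def make(ids, entry, exit_, event, mask):
        d = pd.DataFrame({
            "id": np.asarray(ids)[mask],
            "entry": entry[mask],
            "exit": exit_[mask],
            "event": event[mask].astype(int),
        })
        d = pd.concat([d.reset_index(drop=True), covs[mask].reset_index(drop=True)], axis=1)
        bad = d["entry"] >= d["exit"]
        if bad.any():
            raise ConsistencyError(
                f"entry >= exit for id(s) {d.loc[bad, 'id'].tolist()[:5]} — "
                "same-day ties must be jittered before building risk sets"
            )
        return d

    ids = cohort["id"].to_numpy()
    all_mask = np.ones(len(cohort), dtype=bool)
    zeros = np.zeros(len(cohort))
    died_untreated = died & ~treated

    out = {
        "h1": make(ids, zeros, exit1, treated, all_mask),
        "h2": make(ids, zeros, exit1, died_untreated, all_mask),
        "h3": make(ids, t_treat, t_end, died & treated, treated),
    }
    return out


def summarize_state_flow(
    cohort: pd.DataFrame, admin_censor_days: float = ADMIN_CENSOR_DAYS
) -> StateFlowSummary:
    """Count patients entering/staying in each state and each transition."""
    if len(cohort) == 0:
        return StateFlowSummary(0, 0, 0, 0, 0, 0, 0, 0, 0)
    t_treat = cohort["t_treat"].to_numpy(dtype=float)
    t_death = cohort["t_death"].to_numpy(dtype=float)
    t_end = follow_up_end(cohort, admin_censor_days).to_numpy(dtype=float)

    treated = ~np.isnan(t_treat) & (t_treat <= t_end)
    died = ~np.isnan(t_death) & (t_death <= admin_censor_days)

    x = int(treated.sum())
    y = int((died & ~treated).sum())
    z = int((died & treated).sum())
    N1 = len(cohort)
    return StateFlowSummary(
        N1=N1, n1=N1 - x - y, x=x, y=y,
        N2=x, n2=x - z, z=z,
        N3=y + z, n3=y + z,
    )


# ---------------------------------------------------------------------------
# long-format I/O (conventional multistate layout)
# ---------------------------------------------------------------------------

def write_transition_csv(datasets: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for trans in TRANSITIONS:
        d = datasets[trans].copy()
        d.insert(1, "trans", trans)
        frames.append(d)
    long = pd.concat(frames, ignore_index=True)
    long = long.rename(columns={"entry": "Tstart", "exit": "Tstop", "event": "status"})
    long.to_csv(path, index=False, na_rep="")


def read_transition_csv(path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path)
    out = {}
    for trans, d in long.groupby("trans"):
        d = d.drop(columns=["trans"]).rename(
            columns={"Tstart": "entry", "Tstop": "exit", "status": "event"}
        )
        out[trans] = d.reset_index(drop=True)
    return out
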