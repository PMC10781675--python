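"""Synthetic registry-like cohorts from a known three-state Markov process.

The generator draws covariates from stated marginal distributions, then event
histories from covariate-specific transition hazards: latent times to
treatment (h1) and to pre-treatment death (h2) by inverse transform, first
event wins; treated patients get a post-treatment death time from h3
conditional on being alive at treatment on the shared time-since-diagnosis
clock (clock-forward; a clock-reset option exists but is off by default).
Everything past the administrative horizon (365.24 days) is censored.

Because the data-generating hazards are known, the module can also integrate
them into exact occupancy truth curves (`truth_occupancy`) and empirical
microsimulation curves (`microsimulate_occupancy`) for parameter-recovery and
oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import design as dz
from .hazards import ConstantHazard, SimulationError, hazard_from_config
from .occupancy_core import integrate_occupancy, state_probs_at

__all__ = [
    "SimulationParams",
    "TruthCurves",
    "ConfigurationError",
    "generate_covariates",
    "simulate_event_history",
    "simulate_cohort",
    "truth_occupancy",
    "microsimulate_occupancy",
    "colon_stage4_like",
    "without_deprivation_effects",
    "write_cohort_csv",
    "read_cohort_csv",
]

TRANSITIONS = ("h1", "h2", "h3")

COHORT_COLUMNS = [
    "id", "age", "sex", "ethnicity", "imd_quintile",
    "hf", "mi", "diab", "copd", "route", "site", "stage",
    "diag_year", "t_treat", "t_death", "t_censor",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _check_probs(name: str, probs: dict) -> None:
    p = np.array(list(probs.values()), dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ConfigurationError(
            f"marginal '{name}': probabilities must be >= 0 and sum to 1 (got sum {p.sum()!r})"
        )


@dataclass
class SimulationParams:
    """Full specification of the data-generating process.

    ``baseline`` maps each transition to a hazard config
    (``{"family": "constant"|"weibull"|"spline", ...}``, rates in events/day);
    ``effects`` maps each transition to log hazard ratios keyed by design
    column names (e.g. ``"imd_quintile[5]"``, ``"sex[women]"``, ``"copd"``,
    ``"route[emergency]"``) plus the special key ``"age_per10"`` — a linear
    log-HR per 10 years of age centred at 75.
    """

    n_patients: int
    seed: int
    baseline: dict
    effects: dict = field(default_factory=lambda: {t: {} for t in TRANSITIONS})
    marginals: dict = field(default_factory=dict)
    age: dict = field(default_factory=lambda: {"mean": 72.0, "sd": 12.0})
    admin_censor_days: float = 365.24
    same_day_fraction: float = 0.05
    clock_reset: bool = False
    diag_years: tuple[int, int] = (2012, 2016)

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigurationError("n_patients: must be >= 0")
        if self.admin_censor_days <= 0:
            raise ConfigurationError("admin_censor_days: must be > 0")
        if not 0.0 <= self.same_day_fraction <= 1.0:
            raise ConfigurationError("same_day_fraction: must be in [0, 1]")
        for t in TRANSITIONS:
            if t not in self.baseline:
                raise ConfigurationError(f"baseline: missing transition '{t}'")
        self.marginals = {**_DEFAULT_MARGINALS, **self.marginals}
        for name in ("sex", "ethnicity", "imd_quintile", "route", "site", "stage", "diag_year"):
            _check_probs(name, self.marginals[name])
        for c in dz.COMORBIDITIES:
            p = self.marginals[c]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"marginal '{c}': prevalence must be in [0, 1]")

    def hazard(self, transition: str):
        cfg = self.baseline[transition]
        return cfg if hasattr(cfg, "cumhaz") else hazard_from_config(cfg)

    # -- config-file round trip ------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {plain(k): plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = plain(dataclasses.asdict(self))
        d["diag_years"] = list(self.diag_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "diag_years" in d:
            d["diag_years"] = tuple(d["diag_years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TruthCurves:
    """Exact occupancy and length of stay from the generating hazards."""

    times: np.ndarray
    p11: np.ndarray
    p12: np.ndarray
    p13: np.ndarray
    l1: float
    l2: float
    horizon: float
    profile: dz.CovariateProfile

    @property
    def l3(self) -> float:
        return self.horizon - self.l1 - self.l2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "p11": self.p11, "p12": self.p12, "p13": self.p13})


_DEFAULT_MARGINALS = {
    "sex": {"men": 0.537, "women": 0.463},
    "ethnicity": {"White": 0.948, "Other": 0.052},
    "imd_quintile": {1: 0.212, 2: 0.222, 3: 0.213, 4: 0.187, 5: 0.166},
    "route": {
        "emergency": 0.282, "gp_referral": 0.240, "inpatient_elective": 0.030,
        "other_outpatient": 0.073, "screening": 0.041, "tww": 0.334,
    },
    "site": {"colon": 1.0, "rectal": 0.0},
    "stage": {"I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.92, "missing": 0.08},
    "diag_year": {y: 0.2 for y in range(2012, 2017)},
    "hf": 0.035, "mi": 0.040, "diab": 0.008, "copd": 0.126,
}


def colon_stage4_like(n_patients: int = 20_000, seed: int = 20124, **overrides) -> SimulationParams:
    """Illustrative advanced-colon-cancer preset.

    Covariate marginals follow the stage IV colon column of the registry
    descriptives (women 46.3%, White 94.8%, emergency route 28.2%, ...).
    Baseline rates are set so that, at the reference covariate profile and
    constant hazards, the pre-treatment death fraction is near one third of
    patients over the year — the level seen in advanced colon cancer — and
    most survivors are treated within a few months.  Deprivation acts with
    most-vs-least hazard ratios 0.8 (treatment), 1.3 (pre-treatment death)
    and 1.2 (post-treatment death), log-linear across quintiles.
    """
    def imd_gradient(hr5: float) -> dict:
        return {f"imd_quintile[{q}]": np.log(hr5) * (q - 1) / 4.0 for q in (2, 3, 4, 5)}

    effects = {
        "h1": {
            **imd_gradient(0.8), "age_per10": -0.10, "sex[women]": 0.02,
            "ethnicity[Other]": -0.05, "hf": -0.10, "mi": -0.05, "diab": -0.08, "copd": -0.08,
            "route[emergency]": 0.10, "route[screening]": 0.15, "route[tww]": 0.10,
            "route[inpatient_elective]": 0.0, "route[other_outpatient]": 0.0,
        },
        "h2": {
            **imd_gradient(1.3), "age_per10": 0.45, "sex[women]": -0.05,
            "ethnicity[Other]": -0.02, "hf": 0.30, "mi": 0.20, "diab": 0.25, "copd": 0.20,
            "route[emergency]": 0.60, "route[screening]": -0.50, "route[tww]": 0.05,
            "route[inpatient_elective]": 0.0, "route[other_outpatient]": 0.0,
        },
        "h3": {
            **imd_gradient(1.2), "age_per10": 0.40, "sex[women]": -0.05,
            "ethnicity[Other]": -0.02, "hf": 0.25, "mi": 0.15, "diab": 0.20, "copd": 0.15,
            "route[emergency]": 0.40, "route[screening]": -0.30, "route[tww]": 0.05,
            "route[inpatient_elective]": 0.0, "route[other_outpatient]": 0.0,
        },
    }
    params = dict(
        n_patients=n_patients,
        seed=seed,
        baseline={
            "h1": {"family": "constant", "rate": 0.011},
            "h2": {"family": "constant", "rate": 0.0056},
            "h3": {"family": "weibull", "shape": 0.85, "rate": 0.0034},
        },
        effects=effects,
        age={"mean": 72.0, "sd": 12.0},
        same_day_fraction=0.05,
    )
    params.update(overrides)
    return SimulationParams(**params)


def without_deprivation_effects(params: SimulationParams) -> SimulationParams:
    """Copy of ``params`` with every deprivation log-HR set to zero."""
    effects = {
        t: {k: (0.0 if k.startswith("imd_quintile[") else v) for k, v in eff.items()}
        for t, eff in params.effects.items()
    }
    return dataclasses.replace(params, effects=effects)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _rngs(params: SimulationParams) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(3)]


def generate_covariates(params: SimulationParams) -> pd.DataFrame:
    """Draw one row of covariates per patient from the stated marginals."""
    rng = _rngs(params)[0]
    n = params.n_patients
    m = params.marginals

    def draw_cat(name):
        levels = list(m[name].keys())
        probs = np.array(list(m[name].values()), dtype=float)
        return rng.choice(levels, size=n, p=probs / probs.sum())

    mu, sd = float(params.age["mean"]), float(params.age["sd"])
    a, b = (18.0 - mu) / sd, (99.0 - mu) / sd
    age = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)

    df = pd.DataFrame({
        "id": np.arange(n, dtype=int),
        "age": age,
        "sex": draw_cat("sex"),
        "ethnicity": draw_cat("ethnicity"),
        "imd_quintile": draw_cat("imd_quintile").astype(int) if n else np.array([], dtype=int),
        "hf": (rng.random(n) < m["hf"]).astype(int),
        "mi": (rng.random(n) < m["mi"]).astype(int),
        "diab": (rng.random(n) < m["diab"]).astype(int),
        "copd": (rng.random(n) < m["copd"]).astype(int),
        "route": draw_cat("route"),
        "site": draw_cat("site"),
        "stage": draw_cat("stage"),
        "diag_year": draw_cat("diag_year").astype(int) if n else np.array([], dtype=int),
    })
    return df


def _linear_predictor(covs: pd.DataFrame, effects: dict) -> np.ndarray:
    """Log hazard-ratio offset per patient for one transition."""
    lp = np.zeros(len(covs))
    for key, loghr in effects.items():
        if loghr == 0.0:
            continue
        if key == "age_per10":
            lp += loghr * (covs["age"].to_numpy(dtype=float) - 75.0) / 10.0
        elif key.startswith("imd_quintile["):
            lp += loghr * (covs["imd_quintile"].to_numpy() == int(key[13:-1]))
        elif key.startswith("route["):
            lp += loghr * (covs["route"].to_numpy() == key[6:-1])
        elif key == "sex[women]":
            lp += loghr * (covs["sex"].to_numpy() == "women")
        elif key == "ethnicity[Other]":
            lp += loghr * (covs["ethnicity"].to_numpy() == "Other")
        elif key in dz.COMORBIDITIES:
            lp += loghr * covs[key].to_numpy(dtype=float)
        else:
            raise ConfigurationError(f"effects: unknown covariate key '{key}'")
    return lp


def _profile_lp(profile: dz.CovariateProfile, effects: dict) -> float:
    return float(_linear_predictor(profile.as_frame(), effects)[0])


# ---------------------------------------------------------------------------
# event histories
# ---------------------------------------------------------------------------

def simulate_event_history(covariates: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Attach t_treat / t_death / t_censor columns drawn from the process."""
    _, rng, rng_tie = _rngs(params)
    n = len(covariates)
    T = params.admin_censor_days
    out = covariates.copy()

    base = {t: params.hazard(t) for t in TRANSITIONS}
    for t in TRANSITIONS:
        H = np.asarray(base[t].cumhaz(np.array([T])))
        if not np.all(np.isfinite(H)):
            raise SimulationError(f"transition '{t}': non-finite cumulative hazard at the horizon")
    lp = {t: _linear_predictor(covariates, params.effects[t]) for t in TRANSITIONS}

    e1 = rng.exponential(size=n) * np.exp(-lp["h1"])
    e2 = rng.exponential(size=n) * np.exp(-lp["h2"])
    u3 = rng.exponential(size=n) * np.exp(-lp["h3"])
    with np.errstate(over="ignore", divide="ignore"):
        t1 = np.asarray(base["h1"].inverse_cumhaz(e1), dtype=float)
        t2 = np.asarray(base["h2"].inverse_cumhaz(e2), dtype=float)

    treated = (t1 < t2) & (t1 <= T)
    died_untreated = (t2 <= t1) & (t2 <= T)

    t_treat = np.where(treated, t1, np.nan)
    t_death = np.where(died_untreated, t2, np.nan)

    if np.any(treated):
        u = t1[treated]
        h3 = base["h3"]
        with np.errstate(over="ignore", divide="ignore"):
            if params.clock_reset:
                t3 = u + np.asarray(h3.inverse_cumhaz(u3[treated]), dtype=float)
            else:
                t3 = np.asarray(
                    h3.inverse_cumhaz(np.asarray(h3.cumhaz(u)) + u3[treated]), dtype=float
                )
        died_after = t3 <= T
        td = np.full(n, np.nan)
        td[np.flatnonzero(treated)[died_after]] = t3[died_after]
        t_death = np.where(np.isnan(t_death), td, t_death)

    # same-day ties: a fraction of treated patients recorded on the diagnosis day
    if params.same_day_fraction > 0 and np.any(treated):
        tie = treated & (rng_tie.random(n) < params.same_day_fraction)
        t_treat[tie] = 0.0

    out["t_treat"] = t_treat
    out["t_death"] = t_death
    out["t_censor"] = T
    return out


def simulate_cohort(params: SimulationParams) -> pd.DataFrame:
    return simulate_event_history(generate_covariates(params), params)


# ---------------------------------------------------------------------------
# truth curves and microsimulation oracle
# ---------------------------------------------------------------------------

def _profile_hazard_fns(params: SimulationParams, profile: dz.CovariateProfile):
    base = {t: params.hazard(t) for t in TRANSITIONS}
    lps = {t: _profile_lp(profile, params.effects[t]) for t in TRANSITIONS}

    def H(t):
        return lambda u: np.asarray(base[t].cumhaz(u)) * np.exp(lps[t])

    def h1(u):
        return np.asarray(base["h1"].hazard(u)) * np.exp(lps["h1"])

    return H("h1"), H("h2"), H("h3"), h1


def truth_occupancy(
    params: SimulationParams,
    profile: dz.CovariateProfile | None = None,
    grid: np.ndarray | None = None,
    subnodes: int = 32,
) -> TruthCurves:
    """Deterministic occupancy truth for one covariate profile.

    Integrates the generator's own hazards with the same quadrature used by
    the estimation path, but with true parameters.
    """
    if profile is None:
        profile = dz.reference_profile()
    if grid is None:
        grid = np.linspace(0.0, params.admin_censor_days, 13)
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending and start at 0")
    H1, H2, H3, h1 = _profile_hazard_fns(params, profile)
    p11, p12, p13 = state_probs_at(H1, H2, H3, h1, grid, subnodes=subnodes)
    horizon = float(grid[-1])
    l1, l2 = integrate_occupancy(H1, H2, H3, h1, horizon, subnodes=subnodes)
    return TruthCurves(times=grid, p11=p11, p12=p12, p13=p13, l1=l1, l2=l2,
                       horizon=horizon, profile=profile)


def microsimulate_occupancy(
    params: SimulationParams,
    profile: dz.CovariateProfile,
    times: np.ndarray,
    n_paths: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical occupancy at ``times`` from simulated paths at one profile.

    A Monte-Carlo oracle: every path carries the profile's covariates, so the
    empirical state fractions converge to the true occupancy at binomial rate.
    """
    covs = profile.as_frame().iloc[np.zeros(n_paths, dtype=int)].reset_index(drop=True)
    covs["id"] = np.arange(n_paths)
    p = dataclasses.replace(params, n_patients=n_paths, seed=seed, same_day_fraction=0.0)
    sim = simulate_event_history(covs, p)
    t_treat = sim["t_treat"].to_numpy()
    t_death = sim["t_death"].to_numpy()
    rows = []
    for t in np.asarray(times, dtype=float):
        treated = (t_treat <= t) & ~np.isnan(t_treat)
        dead = (t_death <= t) & ~np.isnan(t_death)
        p12 = np.mean(treated & ~dead)
        p13 = np.mean(dead)
        rows.append({"time": t, "p11": 1.0 - p12 - p13, "p12": p12, "p13": p13})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("t_treat", "t_death"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
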