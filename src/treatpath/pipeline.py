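"""Desk-scale orchestration of the full multistate treatment-inequality study.

One call runs: cohort (simulated or read from CSV) -> inclusion filters ->
site x stage strata -> same-day jitter -> transition risk sets -> df-selected
Royston-Parmar fits -> hazard-ratio tables -> occupancy / length-of-stay
predictions for the least and most deprived reference profiles -> monthly
deprivation contrasts.  Sensitivity runs repeat the analysis on the
missing-stage stratum, a diagnosis-period subset, and screening vs
non-screening strata.

Everything is deterministic given the config seeds: per-stratum jitter and
parameter-draw seeds are spawned from the master seed in a fixed order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import msm, prep, rp
from . import design as dz
from .simulate import SimulationParams, read_cohort_csv, simulate_cohort

__all__ = [
    "AnalysisConfig", "StratumResult", "StudyReport",
    "describe_cohort", "run_analysis", "run_sensitivity", "write_report",
]

TRANSITIONS = ("h1", "h2", "h3")


@dataclass
class AnalysisConfig:
    """Settings for one study run; every field has a documented default."""

    cohort_csv: str | None = None
    sim_params: SimulationParams | None = None
    sites: tuple[str, ...] = ("colon",)
    stages: tuple[str, ...] = ("I", "II", "III", "IV")
    period: tuple[int, int] | None = None          # (first, last) diagnosis year
    screening_only: bool | None = None             # True / False restricts by route
    df_grid: tuple[int, ...] = (1, 2, 3)
    criterion: str = "both"
    covariates: tuple[str, ...] = dz.DEFAULT_COVARIATES
    quintiles: tuple[int, int] = (1, 5)            # (least, most) deprived to contrast
    n_months: int = 12
    horizon: float = msm.HORIZON_DAYS
    n_draws: int = 1000
    seed: int = 0
    min_events: int = 10
    outdir: str | None = None
    sensitivity_period: tuple[int, int] = (2015, 2016)

    def __post_init__(self):
        if (self.cohort_csv is None) == (self.sim_params is None):
            raise ValueError("give exactly one of cohort_csv or sim_params")
        if self.horizon > 365.24 + 1e-9:
            raise ValueError("horizon cannot exceed the administrative censoring time")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("sim_params") is not None:
            doc["sim_params"] = SimulationParams.from_dict(doc["sim_params"])
        for key in ("sites", "stages", "df_grid", "covariates", "quintiles",
                    "period", "sensitivity_period"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class StratumResult:
    name: str
    site: str
    stage: str
    n: int
    descriptives: pd.DataFrame | None = None
    flow: prep.StateFlowSummary | None = None
    selections: dict[str, pd.DataFrame] = field(default_factory=dict)
    fits: dict[str, rp.RPFit] = field(default_factory=dict)
    hr_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    occupancy: dict[int, msm.OccupancyResult] = field(default_factory=dict)
    length_of_stay: dict[int, msm.LengthOfStay] = field(default_factory=dict)
    contrast_occupancy: pd.DataFrame | None = None
    contrast_los: pd.DataFrame | None = None
    skipped: str | None = None


@dataclass
class StudyReport:
    config: AnalysisConfig
    exclusions: dict[str, int]
    strata: dict[str, StratumResult]
    log: list[dict]


def describe_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style descriptives: median (IQR) for age, n (%) for categories.

    Quantiles use linear interpolation between order statistics.
    """
    rows = []
    n = len(cohort)
    if n == 0:
        return pd.DataFrame(columns=["variable", "level", "n", "pct", "median", "q1", "q3"])
    q1, med, q3 = np.quantile(cohort["age"].to_numpy(dtype=float), [0.25, 0.5, 0.75])
    rows.append({"variable": "age", "level": "", "n": n, "pct": np.nan,
                 "median": med, "q1": q1, "q3": q3})
    for var in ("sex", "ethnicity", "imd_quintile", "route", "stage"):
        if var not in cohort.columns:
            continue
        counts = cohort[var].value_counts()
        for level, cnt in counts.items():
            rows.append({"variable": var, "level": str(level), "n": int(cnt),
                         "pct": 100.0 * cnt / n, "median": np.nan, "q1": np.nan, "q3": np.nan})
    for c in dz.COMORBIDITIES:
        if c in cohort.columns:
            cnt = int(cohort[c].sum())
            rows.append({"variable": c, "level": "1", "n": cnt, "pct": 100.0 * cnt / n,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
    return pd.DataFrame(rows)


def _load_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.sim_params is not None:
        return simulate_cohort(config.sim_params)
    return read_cohort_csv(config.cohort_csv)


def _analyse_stratum(
    sub: pd.DataFrame,
    name: str,
    site: str,
    stage: str,
    config: AnalysisConfig,
    jitter_seed: int,
    draw_seed: int,
    log: list[dict],
) -> StratumResult:
    res = StratumResult(name=name, site=site, stage=stage, n=len(sub))
    if len(sub) == 0:
        res.skipped = "empty stratum"
        log.append({"stratum": name, "event": "skipped", "reason": res.skipped})
        return res

    res.descriptives = describe_cohort(sub)
    jittered = prep.jitter_same_day(sub, seed=jitter_seed)
    res.flow = prep.summarize_state_flow(jittered)
    datasets = prep.build_transition_datasets(jittered)

    counts = {t: int(datasets[t]["event"].sum()) for t in TRANSITIONS}
    thin = [t for t, c in counts.items() if c < config.min_events]
    if thin:
        res.skipped = f"fewer than {config.min_events} events on {thin} (counts {counts})"
        log.append({"stratum": name, "event": "skipped", "reason": res.skipped})
        return res

    covs = tuple(c for c in config.covariates if c in sub.columns)
    for t in TRANSITIONS:
        try:
            sel = rp.select_df(datasets[t], dfs=config.df_grid,
                               criterion=config.criterion, covariates=covs, transition=t)
        except rp.FitError as exc:
            res.skipped = f"fit failure on {t}: {exc}"
            log.append({"stratum": name, "event": "fit_failure", "transition": t, "reason": str(exc)})
            return res
        res.selections[t] = sel.table
        res.fits[t] = sel.best_fit
        res.hr_tables[t] = rp.hazard_ratios(sel.best_fit)
        log.append({"stratum": name, "event": "df_selected", "transition": t,
                    "df": sel.chosen_df, "aic_choice": sel.table.attrs["aic_choice"],
                    "bic_choice": sel.table.attrs["bic_choice"],
                    "converged": bool(sel.best_fit.converged)})

    grid = msm.monthly_grid(config.n_months)
    for q in config.quintiles:
        profile = dz.reference_profile(imd_quintile=q)
        res.occupancy[q] = msm.occupancy(res.fits, profile, grid=grid,
                                         n_draws=config.n_draws, seed=draw_seed)
        res.length_of_stay[q] = msm.length_of_stay(res.fits, profile, horizon=config.horizon,
                                                   n_draws=config.n_draws, seed=draw_seed)
    q_least, q_most = config.quintiles
    months = grid[1:]
    res.contrast_occupancy = msm.contrast(res.occupancy[q_most], res.occupancy[q_least], months)
    res.contrast_los = msm.contrast_length_of_stay(res.length_of_stay[q_most],
                                                   res.length_of_stay[q_least])
    return res


def run_analysis(config: AnalysisConfig) -> StudyReport:
    """Run the full study: filter, stratify, fit, predict, contrast."""
    raw = _load_cohort(config)
    cohort, tally = prep.apply_inclusion_filters(raw)
    if config.period is not None and "diag_year" in cohort.columns:
        lo, hi = config.period
        cohort = cohort[cohort["diag_year"].between(lo, hi)].reset_index(drop=True)
    if config.screening_only is not None:
        mask = cohort["route"] == "screening"
        cohort = cohort[mask if config.screening_only else ~mask].reset_index(drop=True)

    log: list[dict] = [{"event": "filtered", "exclusions": tally, "n": len(cohort)}]
    strata: dict[str, StratumResult] = {}
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * len(config.sites) * len(config.stages))
    i = 0
    for site in config.sites:
        for stage in config.stages:
            name = f"{site}_stage_{stage}"
            sub = cohort[(cohort["site"] == site) & (cohort["stage"].astype(str) == stage)]
            jitter_seed = int(children[i].generate_state(1)[0] % (2**31))
            draw_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
            i += 2
            strata[name] = _analyse_stratum(sub.reset_index(drop=True), name, site, stage,
                                            config, jitter_seed, draw_seed, log)
    report = StudyReport(config=config, exclusions=tally, strata=strata, log=log)
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def run_sensitivity(config: AnalysisConfig) -> dict[str, StudyReport]:
    """The three sensitivity runs, shape-compatible with the base report:

    ``missing_stage`` — the missing-stage stratum analysed separately;
    ``period`` — restriction to the contemporary diagnosis years;
    ``screening`` / ``non_screening`` — stratification by screening route.
    """
    out: dict[str, StudyReport] = {}
    base_out = config.outdir

    def sub(name: str, **changes) -> AnalysisConfig:
        outdir = str(Path(base_out) / name) if base_out else None
        return dataclasses.replace(config, outdir=outdir, **changes)

    out["missing_stage"] = run_analysis(sub("missing_stage", stages=("missing",)))
    out["period"] = run_analysis(sub("period", period=config.sensitivity_period))
    out["screening"] = run_analysis(sub("screening", screening_only=True))
    out["non_screening"] = run_analysis(sub("non_screening", screening_only=False))
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_report(report: StudyReport, outdir) -> None:
    """Write all tables as CSV (fits as JSON) under one directory per stratum."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "run_log.json", "w") as fh:
        json.dump(report.log, fh, indent=1, default=str)
    pd.DataFrame([report.exclusions]).to_csv(root / "exclusions.csv", index=False)
    for name, res in report.strata.items():
        d = root / name
        d.mkdir(exist_ok=True)
        if res.skipped is not None:
            (d / "SKIPPED.txt").write_text(res.skipped + "\n")
            continue
        res.descriptives.to_csv(d / "descriptives.csv", index=False)
        pd.DataFrame([dataclasses.asdict(res.flow)]).to_csv(d / "state_flow.csv", index=False)
        for t in TRANSITIONS:
            res.selections[t].to_csv(d / f"selection_{t}.csv", index=False)
            res.hr_tables[t].to_csv(d / f"hr_{t}.csv", index=False)
            rp.fit_to_json(res.fits[t], d / f"fit_{t}.json")
        for q, occ in res.occupancy.items():
            occ.to_frame().to_csv(d / f"occupancy_q{q}.csv", index=False)
        for q, los in res.length_of_stay.items():
            los.to_frame().to_csv(d / f"los_q{q}.csv", index=False)
        res.contrast_occupancy.to_csv(d / "contrast_occupancy.csv", index=False)
        res.contrast_los.to_csv(d / "contrast_los.csv", index=False)
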