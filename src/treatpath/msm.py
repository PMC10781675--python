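"""Markov illness-death predictions from three fitted transition models.

State-occupancy probabilities starting in state 1 (alive, untreated) at
diagnosis:

    P11(t) = exp(-[H1(t|x) + H2(t|x)])
    P12(t) = int_0^t P11(u) h1(u|x) exp(-[H3(t|x) - H3(u|x)]) du
    P13(t) = 1 - P11(t) - P12(t)

computed by the shared Gauss-Legendre integral (progressive structure: no
recovery transitions, so no general ODE solver is needed — an ODE-based
cross-check lives in the test suite).  Restricted lengths of stay are the
time-integrals of the occupancy curves up to a horizon; "days of life lost"
is the horizon minus the expected days alive.

Uncertainty comes from multivariate-normal parameter simulation: ``n_draws``
vectors are drawn around each transition's (gamma, beta) from its fitted
covariance (independently across transitions, which were fitted separately),
all curves are recomputed per draw, and pointwise 2.5/97.5 percentiles form
the bands.  Contrasts (most vs least deprived) difference the paired draws,
so two results computed with the same seed yield coherent contrast intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as dz
from .occupancy_core import integrate_occupancy, state_probs_at
from .rp import RPFit

__all__ = [
    "OccupancyResult", "LengthOfStay", "monthly_grid",
    "occupancy", "length_of_stay", "contrast", "contrast_length_of_stay",
]

HORIZON_DAYS = 365.24
DAYS_PER_MONTH = 365.24 / 12.0

STATES = ("p11", "p12", "p13")


def monthly_grid(n_months: int = 12) -> np.ndarray:
    """Reporting grid at multiples of 365.24/12 days, starting at 0."""
    return np.arange(n_months + 1) * DAYS_PER_MONTH


class GridMismatchError(ValueError):
    pass


@dataclass
class OccupancyResult:
    times: np.ndarray
    p11: np.ndarray
    p12: np.ndarray
    p13: np.ndarray
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    draws: dict[str, np.ndarray]  # (n_times, n_draws) per state
    profile: dz.CovariateProfile
    n_draws: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, point in zip(STATES, (self.p11, self.p12, self.p13)):
            rows.append(pd.DataFrame({
                "time": self.times, "state": state, "estimate": point,
                "lower": self.lower[state], "upper": self.upper[state],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class LengthOfStay:
    horizon: float
    l1: float
    l2: float
    ci: dict[str, tuple[float, float]]
    draws: dict[str, np.ndarray]
    profile: dz.CovariateProfile
    n_draws: int
    seed: int

    @property
    def l3(self) -> float:
        """Days of life lost up to the horizon."""
        return self.horizon - self.l1 - self.l2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quantity": ["l1", "l2", "l3"],
            "estimate": [self.l1, self.l2, self.l3],
            "lower": [self.ci[q][0] for q in ("l1", "l2", "l3")],
            "upper": [self.ci[q][1] for q in ("l1", "l2", "l3")],
        })


def _as_fit_triple(fits) -> tuple[RPFit, RPFit, RPFit]:
    if isinstance(fits, dict):
        return fits["h1"], fits["h2"], fits["h3"]
    return tuple(fits)


def _draw_thetas(fits, n_draws: int, seed: int):
    """One MVN parameter matrix per transition, independent across transitions.

    Draws depend only on the fits, n_draws and seed — never on the profile —
    so calls for different profiles are paired draw-by-draw.
    """
    rng = np.random.default_rng(seed)
    return [f.draw_parameters(n_draws, rng) for f in _as_fit_triple(fits)]


def _fns(fits, profile, thetas=None):
    f1, f2, f3 = _as_fit_triple(fits)
    th = thetas if thetas is not None else [None, None, None]
    return (
        lambda t: f1.cumhaz(profile, t, th[0]),
        lambda t: f2.cumhaz(profile, t, th[1]),
        lambda t: f3.cumhaz(profile, t, th[2]),
        lambda t: f1.hazard(profile, t, th[0]),
    )


def occupancy(
    fits,
    profile: dz.CovariateProfile,
    grid: np.ndarray | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    subnodes: int = 32,
) -> OccupancyResult:
    """State-occupancy probabilities with percentile confidence bands."""
    grid = monthly_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("grid must start at 0 (the diagnosis time)")
    point = state_probs_at(*_fns(fits, profile), grid, subnodes=subnodes)

    draws: dict[str, np.ndarray] = {}
    lower: dict[str, np.ndarray] = {}
    upper: dict[str, np.ndarray] = {}
    if n_draws > 0:
        thetas = _draw_thetas(fits, n_draws, seed)
        d11, d12, d13 = state_probs_at(*_fns(fits, profile, thetas), grid, subnodes=subnodes)
        for state, d in zip(STATES, (d11, d12, d13)):
            draws[state] = d
            lower[state] = np.clip(np.percentile(d, 2.5, axis=1), 0.0, 1.0)
            upper[state] = np.clip(np.percentile(d, 97.5, axis=1), 0.0, 1.0)
    else:
        for state, p in zip(STATES, point):
            draws[state] = p[:, None]
            lower[state] = p.copy()
            upper[state] = p.copy()

    return OccupancyResult(
        times=grid, p11=point[0], p12=point[1], p13=point[2],
        lower=lower, upper=upper, draws=draws,
        profile=profile, n_draws=n_draws, seed=seed,
    )


def length_of_stay(
    fits,
    profile: dz.CovariateProfile,
    horizon: float = HORIZON_DAYS,
    n_draws: int = 1000,
    seed: int = 0,
    n_panels: int = 12,
    subnodes: int = 32,
) -> LengthOfStay:
    """Expected days in each state up to ``horizon`` with percentile CIs.

    Sharing ``seed`` with :func:`occupancy` reuses the same parameter draws,
    so occupancy bands and length-of-stay intervals are coherent.
    """
    l1, l2 = integrate_occupancy(*_fns(fits, profile), horizon,
                                 n_panels=n_panels, subnodes=subnodes)
    draws: dict[str, np.ndarray] = {"l1": np.array([l1]), "l2": np.array([l2])}
    if n_draws > 0:
        thetas = _draw_thetas(fits, n_draws, seed)
        dl1, dl2 = integrate_occupancy(*_fns(fits, profile, thetas), horizon,
                                       n_panels=n_panels, subnodes=subnodes)
        draws = {"l1": dl1, "l2": dl2}
    draws["l3"] = horizon - draws["l1"] - draws["l2"]
    ci = {q: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for q, v in draws.items()}
    return LengthOfStay(horizon=float(horizon), l1=float(l1), l2=float(l2), ci=ci,
                        draws=draws, profile=profile, n_draws=n_draws, seed=seed)


def _check_paired(a, b):
    if a.n_draws != b.n_draws or a.seed != b.seed:
        raise GridMismatchError("contrasts need results computed with the same n_draws and seed")


def contrast(result_a: OccupancyResult, result_b: OccupancyResult,
             times: np.ndarray | None = None) -> pd.DataFrame:
    """Differences (A - B) in occupancy with paired percentile intervals."""
    _check_paired(result_a, result_b)
    if result_a.times.shape != result_b.times.shape or np.any(result_a.times != result_b.times):
        raise GridMismatchError("occupancy results were computed on different grids")
    times = result_a.times if times is None else np.asarray(times, dtype=float)
    idx = np.searchsorted(result_a.times, times)
    if np.any(idx >= result_a.times.size) or np.any(np.abs(result_a.times[idx] - times) > 1e-9):
        raise GridMismatchError("requested times are not on the computed grid")
    rows = []
    points_a = dict(zip(STATES, (result_a.p11, result_a.p12, result_a.p13)))
    points_b = dict(zip(STATES, (result_b.p11, result_b.p12, result_b.p13)))
    for state in STATES:
        diff_draws = result_a.draws[state][idx] - result_b.draws[state][idx]
        rows.append(pd.DataFrame({
            "quantity": state,
            "time": times,
            "difference": points_a[state][idx] - points_b[state][idx],
            "lower": np.percentile(diff_draws, 2.5, axis=1),
            "upper": np.percentile(diff_draws, 97.5, axis=1),
        }))
    return pd.concat(rows, ignore_index=True)


def contrast_length_of_stay(a: LengthOfStay, b: LengthOfStay) -> pd.DataFrame:
    """Differences (A - B) in lengths of stay with paired percentile intervals."""
    _check_paired(a, b)
    if a.horizon != b.horizon:
        raise GridMismatchError("length-of-stay contrasts need a common horizon")
    rows = []
    for q, pa, pb in (("l1", a.l1, b.l1), ("l2", a.l2, b.l2), ("l3", a.l3, b.l3)):
        d = a.draws[q] - b.draws[q]
        rows.append({
            "quantity": q, "time": a.horizon, "difference": pa - pb,
            "lower": float(np.percentile(d, 2.5)), "upper": float(np.percentile(d, 97.5)),
        })
    return pd.DataFrame(rows)
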