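"""Royston-Parmar flexible parametric survival models with delayed entry.

The log cumulative hazard is modelled as a restricted cubic spline in log
time plus a linear predictor:

    log H(t | x) = gamma_0 + s(log t; gamma) + x beta

Covariates act proportionally on the hazard.  With observed (entry, exit,
event) rows the log likelihood is

    l = sum_i d_i [ log s'(log t_i) - log t_i + eta_i ] - exp(eta_i) + exp(eta0_i)

where eta_i is the linear predictor at the exit time, eta0_i its value at the
entry time (the term is present only for entry > 0 and conditions on having
survived to entry — exactly the delayed-entry correction that removes
immortal-time bias for the treatment->death transition), and s' the
derivative of the spline in log time.  Gradient and Hessian are analytic;
optimisation is Newton with step halving, initialised from a regression of
the log Nelson-Aalen cumulative hazard on the spline basis.  The covariance
is the inverse observed information at the optimum.

With one degree of freedom (no interior knots) the model is exactly a Weibull
regression: log H linear in log time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as dz
from .splines import SplineSpec, knots_from_quantiles, rcs_basis

__all__ = [
    "RPFit", "FitError", "fit", "select_df", "SelectionResult",
    "predict_cumhaz", "predict_hazard", "predict_survival", "hazard_ratios",
    "fit_to_json", "fit_from_json",
]


class FitError(RuntimeError):
    pass


@dataclass
class RPFit:
    """A fitted flexible parametric transition model."""

    gamma: np.ndarray                 # intercept + df baseline spline coefficients
    beta: np.ndarray                  # covariate log hazard ratios
    beta_names: list[str]
    vcov: np.ndarray                  # joint covariance of (gamma, beta)
    loglik: float
    baseline_spec: SplineSpec
    age_spec: SplineSpec | None
    converged: bool
    n_events: int
    n_rows: int
    gradient_norm: float
    valid_hazard: bool = True         # s'(log t) > 0 over the observed event-time range
    transition: str | None = None

    @property
    def df_baseline(self) -> int:
        return self.baseline_spec.df

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.gamma, self.beta])

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(max(self.n_events, 1))

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    # -- prediction helpers (theta_cols: optional draws, shape (p, m)) ------
    def _eta_parts(self, times: np.ndarray):
        t = np.asarray(times, dtype=float)
        if np.any(t <= 0):
            raise ValueError("prediction times must be > 0")
        B, D = rcs_basis(np.log(t), self.baseline_spec)
        return B, D

    def linear_predictor_design(self, profile: dz.CovariateProfile) -> np.ndarray:
        return dz.profile_design(profile, self.beta_names, self.age_spec)

    def cumhaz(self, profile: dz.CovariateProfile, times, theta=None) -> np.ndarray:
        B, _ = self._eta_parts(times)
        x = self.linear_predictor_design(profile)
        th = self.theta if theta is None else np.asarray(theta)
        C = np.column_stack([np.ones(B.shape[0]), B])
        k = self.gamma.size
        if th.ndim == 1:
            eta = C @ th[:k] + x @ th[k:]
        else:
            eta = C @ th[:k, :] + (x @ th[k:, :])
        # cap the log cumulative hazard: extreme MVN draws from ill-conditioned
        # covariances otherwise overflow; exp(80) already means certain death
        return np.exp(np.minimum(eta, 80.0))

    def hazard(self, profile: dz.CovariateProfile, times, theta=None) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        B, D = self._eta_parts(times)
        th = self.theta if theta is None else np.asarray(theta)
        k = self.gamma.size
        H = self.cumhaz(profile, times, theta)
        if th.ndim == 1:
            sprime = D @ th[1:k]
            return H * sprime / t
        sprime = D @ th[1:k, :]
        return H * sprime / t[:, None]

    def survival(self, profile: dz.CovariateProfile, times, theta=None) -> np.ndarray:
        return np.exp(-self.cumhaz(profile, times, theta))

    def as_hazard(self, profile: dz.CovariateProfile):
        """The fitted hazard at one profile as a simulation-ready object.

        Folds x beta into the spline intercept, so the generator can draw
        event times from a fitted model (microsimulation cross-checks).
        """
        from .hazards import SplineHazard

        offset = float(self.linear_predictor_design(profile) @ self.beta)
        gamma = self.gamma.copy()
        gamma[0] += offset
        return SplineHazard(gamma=tuple(gamma), spec=self.baseline_spec)

    def draw_parameters(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """MVN parameter draws around (gamma, beta); shape (p, n_draws).

        Uses an eigendecomposition with negative eigenvalues clipped to zero,
        so near-singular information matrices (sparse covariate cells in small
        strata) still yield valid draws.
        """
        evals, evecs = np.linalg.eigh(self.vcov)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        z = rng.standard_normal((self.n_params, n_draws))
        return self.theta[:, None] + root @ z


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _Likelihood:
    def __init__(self, entry, exit_, event, X, spec: SplineSpec):
        y = np.log(exit_)
        B, D = rcs_basis(y, spec)
        n = y.size
        self.C = np.column_stack([np.ones(n), B, X])
        self.DG = np.column_stack([np.zeros(n), D, np.zeros_like(X)])
        self.event = event.astype(bool)
        self.logt = y
        trunc = entry > 0
        self.has_trunc = bool(trunc.any())
        if self.has_trunc:
            B0, _ = rcs_basis(np.log(entry[trunc]), spec)
            self.C0 = np.column_stack([np.ones(int(trunc.sum())), B0, X[trunc]])
        self.k = 1 + spec.df
        self.p = self.C.shape[1]

    def value(self, theta):
        eta = self.C @ theta
        sp = self.DG[self.event] @ theta
        if np.any(sp <= 0):
            return -np.inf
        with np.errstate(over="ignore"):
            ll = np.sum(np.log(sp) - self.logt[self.event] + eta[self.event]) - np.sum(np.exp(eta))
            if self.has_trunc:
                ll += np.sum(np.exp(self.C0 @ theta))
        return ll if np.isfinite(ll) else -np.inf

    def value_grad_hess(self, theta):
        eta = self.C @ theta
        Ce = self.C[self.event]
        De = self.DG[self.event]
        sp = De @ theta
        if np.any(sp <= 0):
            return -np.inf, None, None
        with np.errstate(over="ignore"):
            w = np.exp(eta)
        if not np.all(np.isfinite(w)):
            return -np.inf, None, None
        ll = np.sum(np.log(sp) - self.logt[self.event] + eta[self.event]) - np.sum(w)
        g = (De / sp[:, None]).sum(axis=0) + Ce.sum(axis=0) - w @ self.C
        H = (
            -(De / sp[:, None]).T @ (De / sp[:, None])
            - (self.C * w[:, None]).T @ self.C
        )
        if self.has_trunc:
            with np.errstate(over="ignore"):
                w0 = np.exp(self.C0 @ theta)
            if not np.all(np.isfinite(w0)):
                return -np.inf, None, None
            ll += np.sum(w0)
            g += w0 @ self.C0
            H += (self.C0 * w0[:, None]).T @ self.C0
        return ll, g, H


def _nelson_aalen(entry, exit_, event):
    """Left-truncation-aware Nelson-Aalen cumulative hazard at event times."""
    et = np.sort(exit_[event.astype(bool)])
    times, counts = np.unique(et, return_counts=True)
    exit_sorted = np.sort(exit_)
    entry_sorted = np.sort(entry)
    # at risk at t: entered strictly before t and not yet exited (exit >= t)
    n_entered = np.searchsorted(entry_sorted, times, side="left")
    n_exited = np.searchsorted(exit_sorted, times, side="left")
    at_risk = np.maximum(n_entered - n_exited, 1)
    H = np.cumsum(counts / at_risk)
    return times, H


def _initial_theta(like: _Likelihood, entry, exit_, event, spec, n_cov):
    times, H = _nelson_aalen(entry, exit_, event)
    keep = H > 0
    B, _ = rcs_basis(np.log(times[keep]), spec)
    Z = np.column_stack([np.ones(keep.sum()), B])
    coef, *_ = np.linalg.lstsq(Z, np.log(H[keep]), rcond=None)
    return np.concatenate([coef, np.zeros(n_cov)])


def _newton(like: _Likelihood, theta0, max_iter=200, tol=1e-9):
    theta = theta0.copy()
    ll, g, H = like.value_grad_hess(theta)
    if not np.isfinite(ll):
        # fall back to a crude exponential start inside the feasible region
        theta = np.zeros_like(theta0)
        theta[0] = np.log(max(like.event.sum(), 1)) - np.log(np.sum(np.exp(like.logt)))
        theta[1] = 1.0
        ll, g, H = like.value_grad_hess(theta)
        if not np.isfinite(ll):
            raise FitError("could not find a feasible starting point (non-positive spline slope)")
    for _ in range(max_iter):
        ridge = 0.0
        for _try in range(8):
            try:
                delta = np.linalg.solve(-(H - ridge * np.eye(H.shape[0])), g)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None and g @ delta > 0:
                break
            ridge = max(ridge * 10.0, 1e-6 * (1.0 + np.abs(np.diag(H)).max()))
        else:
            delta = g / (1.0 + np.abs(np.diag(H)).max())
        step, ll_new = 1.0, -np.inf
        for _half in range(40):
            ll_new = like.value(theta + step * delta)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        theta = theta + step * delta
        ll_prev = ll
        ll, g, H = like.value_grad_hess(theta)
        gnorm = np.max(np.abs(g)) / (1.0 + abs(ll))
        if gnorm < tol and ll - ll_prev < 1e-9:
            break
    gnorm = np.max(np.abs(g)) / (1.0 + abs(ll))
    return theta, ll, g, H, gnorm


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit(
    data: pd.DataFrame,
    df_baseline: int = 2,
    covariates: tuple[str, ...] | None = None,
    age_spec: SplineSpec | None = None,
    baseline_spec: SplineSpec | None = None,
    transition: str | None = None,
    tol: float = 1e-9,
) -> RPFit:
    """Fit one transition model to a risk-set table.

    ``data`` needs columns entry, exit, event plus any covariates named in
    ``covariates`` (dummy-coded via the shared design; ``()`` fits a baseline
    with no covariates).  Baseline knots default to equally spaced centiles of
    the uncensored log event times with boundary knots at their min/max; age
    knots default to the 5/35/65/95 percentiles of the table's ages.
    """
    entry = data["entry"].to_numpy(dtype=float)
    exit_ = data["exit"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=int)
    if np.any(exit_ <= 0) or np.any(entry < 0) or np.any(entry >= exit_):
        raise ValueError("need 0 <= entry < exit with exit > 0 for every row")
    n_events = int(event.sum())
    if n_events < 1:
        raise FitError("cannot fit a transition with zero events")

    if covariates is None:
        covariates = tuple(c for c in dz.DEFAULT_COVARIATES if c in data.columns)
    if covariates:
        X, names, age_spec = dz.build_design(data, covariates, age_spec)
        # drop empty dummy levels (e.g. no screening route inside a screening
        # stratum): a zero-variance column makes the information singular, and
        # omitting it simply treats that level as the reference
        keep = np.ptp(X, axis=0) > 0
        if not keep.all():
            X = X[:, keep]
            names = [n for n, k in zip(names, keep) if k]
    else:
        X, names, age_spec = np.empty((len(data), 0)), [], None

    if baseline_spec is None:
        baseline_spec = knots_from_quantiles(np.log(exit_[event == 1]), df=df_baseline)

    like = _Likelihood(entry, exit_, event, X, baseline_spec)
    theta0 = _initial_theta(like, entry, exit_, event, baseline_spec, X.shape[1])
    theta, ll, g, H, gnorm = _newton(like, theta0, tol=tol)

    converged = bool(gnorm < 1e-5)
    if not converged:
        raise FitError(f"Newton iteration did not converge (scaled gradient norm {gnorm:.3g})")
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise FitError("observed information is singular at the optimum") from exc
    vcov = 0.5 * (vcov + vcov.T)

    k = baseline_spec.df + 1
    fit_ = RPFit(
        gamma=theta[:k], beta=theta[k:], beta_names=names, vcov=vcov,
        loglik=float(ll), baseline_spec=baseline_spec, age_spec=age_spec,
        converged=converged, n_events=n_events, n_rows=len(data),
        gradient_norm=float(gnorm), transition=transition,
    )
    fit_.valid_hazard = _hazard_positive(fit_, exit_[event == 1])
    return fit_


def _hazard_positive(fit_: RPFit, event_times: np.ndarray, n_grid: int = 200) -> bool:
    """Check s'(log t) > 0 across the observed event-time range."""
    lo, hi = np.log(event_times.min()), np.log(event_times.max())
    grid = np.linspace(lo, hi, n_grid)
    _, D = rcs_basis(grid, fit_.baseline_spec)
    return bool(np.all(D @ fit_.gamma[1:] > 0))


@dataclass
class SelectionResult:
    chosen_df: int
    table: pd.DataFrame
    fits: dict[int, RPFit]
    criterion: str

    @property
    def best_fit(self) -> RPFit:
        return self.fits[self.chosen_df]


def select_df(
    data: pd.DataFrame,
    dfs: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    criterion: str = "both",
    **fit_kwargs,
) -> SelectionResult:
    """Fit a grid of baseline degrees of freedom and pick by AIC/BIC.

    Fits whose spline slope goes non-positive anywhere on the observed
    event-time range (non-physical negative hazards) are excluded from
    selection.  With ``criterion="both"`` the BIC winner is chosen
    (parsimony) and any disagreement with AIC is recorded in the table.
    """
    if not dfs:
        raise ValueError("df grid must be non-empty")
    rows, fits = [], {}
    for df_ in dfs:
        try:
            f = fit(data, df_baseline=df_, **fit_kwargs)
            fits[df_] = f
            rows.append({
                "df": df_, "k": f.n_params, "loglik": f.loglik,
                "aic": f.aic(), "bic": f.bic(),
                "converged": f.converged, "valid_hazard": f.valid_hazard,
            })
        except (FitError, ValueError) as exc:
            rows.append({
                "df": df_, "k": np.nan, "loglik": np.nan, "aic": np.nan, "bic": np.nan,
                "converged": False, "valid_hazard": False, "error": str(exc),
            })
    table = pd.DataFrame(rows)
    ok = table[table["converged"] & table["valid_hazard"]]
    if ok.empty:
        raise FitError("no admissible fit on the df grid")
    aic_df = int(ok.loc[ok["aic"].idxmin(), "df"])
    bic_df = int(ok.loc[ok["bic"].idxmin(), "df"])
    chosen = {"aic": aic_df, "bic": bic_df, "both": bic_df}[criterion]
    table.attrs["aic_choice"] = aic_df
    table.attrs["bic_choice"] = bic_df
    table.attrs["disagreement"] = aic_df != bic_df
    return SelectionResult(chosen_df=chosen, table=table, fits=fits, criterion=criterion)


def exponential_fit(rate: float, effects: dict[str, float] | None = None,
                    t_range: tuple[float, float] = (0.5, 365.24)) -> RPFit:
    """Exactly encode a constant hazard as a one-df fit: log H = log(rate) + log t.

    Useful for closed-form oracles: the estimation path applied to such a fit
    must reproduce the analytic constant-hazard illness-death solution.
    Optional ``effects`` adds exact covariate log-HRs (zero covariance).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0 (a log-linear model cannot encode zero hazard)")
    effects = effects or {}
    names = list(effects.keys())
    p = 2 + len(names)
    spec = SplineSpec((), (np.log(t_range[0]), np.log(t_range[1])))
    return RPFit(
        gamma=np.array([np.log(rate), 1.0]),
        beta=np.array([effects[n] for n in names], dtype=float),
        beta_names=names,
        vcov=np.zeros((p, p)),
        loglik=0.0,
        baseline_spec=spec,
        age_spec=None,
        converged=True,
        n_events=0,
        n_rows=0,
        gradient_norm=0.0,
    )


# ---------------------------------------------------------------------------
# predictions and summaries
# ---------------------------------------------------------------------------

def predict_cumhaz(fit_: RPFit, profile: dz.CovariateProfile, times,
                   horizon: float = 365.24) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if np.any(t > horizon):
        warnings.warn("prediction beyond the administrative horizon extrapolates the spline tails")
    return fit_.cumhaz(profile, t)


def predict_hazard(fit_: RPFit, profile: dz.CovariateProfile, times) -> np.ndarray:
    return fit_.hazard(profile, times)


def predict_survival(fit_: RPFit, profile: dz.CovariateProfile, times) -> np.ndarray:
    return fit_.survival(profile, times)


def hazard_ratios(fit_: RPFit, level: float = 0.95) -> pd.DataFrame:
    """HR = exp(beta) with Wald confidence intervals from the joint vcov."""
    from scipy import stats

    if not fit_.converged:
        raise FitError("hazard ratios require a converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = fit_.gamma.size
    se = fit_.se()[k:]
    with np.errstate(over="ignore"):  # near-empty cells give inf upper bounds
        return pd.DataFrame({
            "term": fit_.beta_names,
            "loghr": fit_.beta,
            "se": se,
            "hr": np.exp(fit_.beta),
            "lo": np.exp(fit_.beta - z * se),
            "hi": np.exp(fit_.beta + z * se),
        })


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def _spec_dict(spec: SplineSpec | None):
    if spec is None:
        return None
    return {
        "interior_knots": list(spec.interior_knots),
        "boundary_knots": list(spec.boundary_knots),
        "transform": spec.transform,
    }


def _spec_from(d):
    if d is None:
        return None
    return SplineSpec(tuple(d["interior_knots"]), tuple(d["boundary_knots"]), d["transform"])


def fit_to_json(fit_: RPFit, path=None) -> str:
    doc = {
        "gamma": fit_.gamma.tolist(),
        "beta": fit_.beta.tolist(),
        "beta_names": fit_.beta_names,
        "vcov": fit_.vcov.tolist(),
        "loglik": fit_.loglik,
        "baseline_spec": _spec_dict(fit_.baseline_spec),
        "age_spec": _spec_dict(fit_.age_spec),
        "converged": fit_.converged,
        "n_events": fit_.n_events,
        "n_rows": fit_.n_rows,
        "gradient_norm": fit_.gradient_norm,
        "valid_hazard": fit_.valid_hazard,
        "transition": fit_.transition,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def fit_from_json(source) -> RPFit:
    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    return RPFit(
        gamma=np.asarray(doc["gamma"]),
        beta=np.asarray(doc["beta"]),
        beta_names=list(doc["beta_names"]),
        vcov=np.asarray(doc["vcov"]),
        loglik=doc["loglik"],
        baseline_spec=_spec_from(doc["baseline_spec"]),
        age_spec=_spec_from(doc["age_spec"]),
        converged=doc["converged"],
        n_events=doc["n_events"],
        n_rows=doc["n_rows"],
        gradient_norm=doc["gradient_norm"],
        valid_hazard=doc["valid_hazard"],
        transition=doc.get("transition"),
    )
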