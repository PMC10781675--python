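"""Restricted (natural) cubic spline bases.

The basis follows the Royston-Parmar convention used for flexible parametric
survival models: for interior knots k_1 < ... < k_m inside boundary knots
(k_min, k_max), the j-th nonlinear column is

    v_j(x) = (x - k_j)_+^3 - lam_j (x - k_min)_+^3 - (1 - lam_j)(x - k_max)_+^3

with lam_j = (k_max - k_j) / (k_max - k_min), preceded by the linear column x.
Each basis function is twice continuously differentiable and exactly linear
beyond the boundary knots, so extrapolated log cumulative hazards stay linear
in log time.  The same basis serves the baseline (x = log time) and the age
covariate (x = age in years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "rcs_basis", "knots_from_quantiles"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for one restricted cubic spline.

    ``df`` (number of basis columns, excluding any intercept) equals the
    number of interior knots plus one.  ``transform`` records the scale the
    spline is evaluated on ("log" for log time, "identity" for age); callers
    are responsible for applying the transform before calling
    :func:`rcs_basis`.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    transform: str = "log"

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
        ks = np.asarray(self.interior_knots, dtype=float)
        if ks.size and (np.any(np.diff(ks) <= 0) or ks[0] <= lo or ks[-1] >= hi):
            raise ValueError(
                "interior knots must be strictly increasing and strictly "
                f"inside the boundary knots; got {self.interior_knots} within ({lo}, {hi})"
            )
        if self.transform not in ("log", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.concatenate(
            [[self.boundary_knots[0]], self.interior_knots, [self.boundary_knots[1]]]
        )


def knots_from_quantiles(
    values: np.ndarray,
    df: int | None = None,
    percentiles: tuple[float, ...] | None = None,
    transform: str = "log",
) -> SplineSpec:
    """Place knots at quantiles of observed values (already on the spline scale).

    Two placement rules are supported:

    * ``df`` given: boundary knots at the min/max, interior knots at ``df - 1``
      equally spaced centiles — the standard rule for the baseline log-time
      spline, applied to uncensored log event times.
    * ``percentiles`` given (e.g. ``(5, 35, 65, 95)`` for the age spline):
      first/last are boundary knots, the rest interior.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values to place knots")
    if (df is None) == (percentiles is None):
        raise ValueError("give exactly one of df or percentiles")
    if percentiles is not None:
        qs = np.percentile(x, percentiles)
        lo, hi, interior = qs[0], qs[-1], tuple(qs[1:-1])
    else:
        if df < 1:
            raise ValueError("df must be >= 1")
        lo, hi = float(x.min()), float(x.max())
        centiles = np.linspace(0, 100, df + 1)[1:-1]
        interior = tuple(np.percentile(x, centiles)) if df > 1 else ()
    # collapse duplicate knots (heavily tied data) by nudging is not attempted;
    # SplineSpec validation will raise, which is the honest failure mode
    return SplineSpec(interior_knots=interior, boundary_knots=(float(lo), float(hi)), transform=transform)


def rcs_basis(x: np.ndarray, spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the restricted cubic spline basis and its analytic derivative.

    Returns ``(B, D)`` with shape ``(n, spec.df)`` each: ``B[:, 0] = x`` and
    ``D = dB/dx``.  With no interior knots the basis degenerates to the single
    linear column ``x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis input contains non-finite values")
    scalar_in = x.ndim == 0
    x = np.atleast_1d(x)
    lo, hi = spec.boundary_knots
    B = np.empty((x.size, spec.df))
    D = np.empty_like(B)
    B[:, 0] = x
    D[:, 0] = 1.0
    if spec.df > 1:
        span = hi - lo
        plo = np.maximum(x - lo, 0.0)
        phi = np.maximum(x - hi, 0.0)
        for j, k in enumerate(spec.interior_knots, start=1):
            lam = (hi - k) / span
            pk = np.maximum(x - k, 0.0)
            B[:, j] = pk**3 - lam * plo**3 - (1.0 - lam) * phi**3
            D[:, j] = 3.0 * (pk**2 - lam * plo**2 - (1.0 - lam) * phi**2)
    if scalar_in:
        return B[0], D[0]
    return B, D
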