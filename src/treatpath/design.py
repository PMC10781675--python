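"""Covariate encoding shared by the generator, the model fits and prediction.

Reference levels follow the study convention: men, White ethnicity, least
deprived quintile (1), no comorbidity, standard GP referral.  Age enters as a
restricted cubic spline with four knots at the 5/35/65/95 percentiles of the
analysis cohort's age distribution (recomputed per stratum), so a fitted
model must carry its age-knot record to make predictions reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineSpec, knots_from_quantiles, rcs_basis

SEX_LEVELS = ("men", "women")
ETHNICITY_LEVELS = ("White", "Other")
IMD_LEVELS = (1, 2, 3, 4, 5)  # 1 = least deprived
ROUTE_LEVELS = (
    "gp_referral",  # reference: standard GP referral
    "emergency",
    "inpatient_elective",
    "other_outpatient",
    "screening",
    "tww",
)
COMORBIDITIES = ("hf", "mi", "diab", "copd")
SITE_LEVELS = ("colon", "rectal")
STAGE_LEVELS = ("I", "II", "III", "IV", "missing")

AGE_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)

DEFAULT_COVARIATES = ("imd_quintile", "age", "sex", "ethnicity") + COMORBIDITIES + ("route",)


@dataclass(frozen=True)
class CovariateProfile:
    """One covariate profile for prediction.

    The default is the reporting reference: a White, male, 75-year-old
    patient without comorbidity diagnosed via standard GP referral; vary
    ``imd_quintile`` for deprivation contrasts.
    """

    age: float = 75.0
    sex: str = "men"
    ethnicity: str = "White"
    imd_quintile: int = 1
    hf: int = 0
    mi: int = 0
    diab: int = 0
    copd: int = 0
    route: str = "gp_referral"

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise ValueError(f"ethnicity must be one of {ETHNICITY_LEVELS}")
        if self.imd_quintile not in IMD_LEVELS:
            raise ValueError(f"imd_quintile must be in {IMD_LEVELS}")
        if self.route not in ROUTE_LEVELS:
            raise ValueError(f"route must be one of {ROUTE_LEVELS}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def reference_profile(imd_quintile: int = 1) -> CovariateProfile:
    return CovariateProfile(imd_quintile=imd_quintile)


def age_spline_spec(ages: np.ndarray) -> SplineSpec:
    """Age spline knots at the 5/35/65/95 percentiles of the cohort's ages."""
    return knots_from_quantiles(np.asarray(ages, float), percentiles=AGE_KNOT_PERCENTILES, transform="identity")


def build_design(
    df: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    age_spec: SplineSpec | None = None,
) -> tuple[np.ndarray, list[str], SplineSpec | None]:
    """Dummy-code covariates into a design matrix (no intercept column).

    Returns ``(X, names, age_spec)``; ``age_spec`` is the spline layout used
    for the age columns (computed from ``df`` when not supplied), or None when
    age is not among the covariates.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "age":
            if age_spec is None:
                age_spec = age_spline_spec(df["age"].to_numpy())
            B, _ = rcs_basis(df["age"].to_numpy(dtype=float), age_spec)
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                names.append(f"age_rcs{j + 1}")
        elif cov == "sex":
            cols.append((df["sex"].to_numpy() == "women").astype(float))
            names.append("sex[women]")
        elif cov == "ethnicity":
            cols.append((df["ethnicity"].to_numpy() == "Other").astype(float))
            names.append("ethnicity[Other]")
        elif cov == "imd_quintile":
            q = df["imd_quintile"].to_numpy()
            for level in IMD_LEVELS[1:]:
                cols.append((q == level).astype(float))
                names.append(f"imd_quintile[{level}]")
        elif cov == "route":
            r = df["route"].to_numpy()
            for level in ROUTE_LEVELS[1:]:
                cols.append((r == level).astype(float))
                names.append(f"route[{level}]")
        elif cov in COMORBIDITIES:
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, age_spec


def profile_design(profile: CovariateProfile, names: list[str], age_spec: SplineSpec | None) -> np.ndarray:
    """Encode one profile into the column layout of a fitted design."""
    df = profile.as_frame()
    x = np.zeros(len(names))
    for i, name in enumerate(names):
        if name.startswith("age_rcs"):
            if age_spec is None:
                raise ValueError("fit has age columns but no age-knot record")
            B, _ = rcs_basis(np.array([profile.age], float), age_spec)
            x[i] = B[0, int(name[len("age_rcs"):]) - 1]
        elif name == "sex[women]":
            x[i] = float(profile.sex == "women")
        elif name == "ethnicity[Other]":
            x[i] = float(profile.ethnicity == "Other")
        elif name.startswith("imd_quintile["):
            x[i] = float(profile.imd_quintile == int(name[13:-1]))
        elif name.startswith("route["):
            x[i] = float(profile.route == name[6:-1])
        elif name in COMORBIDITIES:
            x[i] = float(getattr(profile, name))
        else:
            raise ValueError(f"unknown design column {name!r}")
    return x
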