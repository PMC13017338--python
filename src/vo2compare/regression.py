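"""Covariate regression of inter-equation percent-predicted differences.

For each ordered pair of equations the signed difference in percent
predicted (A − B, continuous scale) is regressed by ordinary least
squares on scaled demographic and anthropometric covariates: age per
decade, BMI per 5 kg/m², female sex (reference male), treadmill mode
(reference cycle), and race indicators (reference white). Coefficients
are therefore read as percentage-point changes in the inter-equation
difference per 10 years of age, per 5 BMI units, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .subjects import Subject

__all__ = ["DESIGN_COLUMNS", "RACE_LEVELS", "DifferenceModelFit", "build_design", "fit_difference_model"]

RACE_LEVELS = ("white", "black", "asian", "other")

DESIGN_COLUMNS = (
    "age_decades",
    "bmi_5units",
    "sex_female",
    "mode_treadmill",
    "race_black",
    "race_asian",
    "race_other",
)


@dataclass(frozen=True)
class DifferenceModelFit:
    """OLS estimates for one pair's difference model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    nobs: int
    rsquared: float


def _race_level(race: str | None) -> str:
    if race is None:
        return "other"
    r = race.strip().lower()
    return r if r in RACE_LEVELS else "other"


def build_design(cohort: list[Subject]) -> pd.DataFrame:
    """One scaled-covariate row per subject, in deterministic column order."""
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for s in cohort:
        if s.age is None or s.height is None or s.weight is None:
            raise ValueError(f"subject {s.id!r} has missing covariates")
        race = _race_level(s.race)
        rows.append(
            {
                "age_decades": s.age / 10.0,
                "bmi_5units": s.bmi / 5.0,
                "sex_female": 1.0 if s.sex == "female" else 0.0,
                "mode_treadmill": 1.0 if s.mode == "treadmill" else 0.0,
                "race_black": 1.0 if race == "black" else 0.0,
                "race_asian": 1.0 if race == "asian" else 0.0,
                "race_other": 1.0 if race == "other" else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS), index=[s.id for s in cohort])


def fit_difference_model(pp_diff, design: pd.DataFrame) -> DifferenceModelFit:
    """OLS fit of a signed percent-predicted difference on the design.

    An intercept is always included. Constant (all-zero) indicator
    columns are dropped — a cohort without, say, any Asian subjects
    simply has no estimate for that level. Genuine collinearity among
    the remaining columns raises with the offending columns named.
    """
    y = np.asarray(pp_diff, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError("pp_diff must be 1-D and match the design length")
    X = design.loc[:, [c for c in design.columns if design[c].nunique() > 1]]
    X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than parameters ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # Name columns whose removal restores full rank.
        collinear = []
        for col in X.columns:
            reduced = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")
    fit = sm.OLS(y, X).fit()
    return DifferenceModelFit(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        conf_int=fit.conf_int(alpha=0.05),
        nobs=int(fit.nobs),
        rsquared=float(fit.rsquared),
    )
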