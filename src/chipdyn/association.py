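"""Covariate models relating CHIP measures to participant characteristics.

Cross-sectional models at each subject's first visit (logistic for CHIP /
large-clone prevalence, linear for log10 VAF) and a longitudinal model of the
dominant clone's change in log10 VAF between the first and last non-zero
measurements.  All models adjust for the first-visit calendar year, use
dummy-coded categoricals, and perform complete-case analysis with logged
exclusion counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelError",
    "AssociationResult",
    "cross_sectional_model",
    "longitudinal_growth_model",
]

logger = logging.getLogger(__name__)

PREVALENCE_OUTCOMES = {"chip_prevalence": "chip_positive",
                       "large_clone_prevalence": "large_clone"}
CONTINUOUS_OUTCOMES = {"log10_vaf"}

DEFAULT_COVARIATES = ("age", "race_ethnicity", "smoking", "bmi")
CATEGORICAL_COVARIATES = {"race_ethnicity", "smoking"}


class ModelError(ValueError):
    """Singular design, separation, or too little usable data."""


@dataclass
class AssociationResult:
    outcome: str
    model: str  # "logistic" | "linear"
    coefficients: pd.DataFrame  # term, estimate, se, p
    n_used: int
    n_excluded_missing: int


def _check_design(df: pd.DataFrame, terms) -> None:
    for term in terms:
        col = df[term]
        if col.nunique(dropna=True) < 2:
            raise ModelError(f"covariate {term!r} is constant in the usable data")


def _formula(outcome_col: str, covariates, extra: tuple[str, ...] = ()) -> str:
    parts = []
    for c in covariates:
        parts.append(f"C({c})" if c in CATEGORICAL_COVARIATES else c)
    parts.extend(extra)
    return f"{outcome_col} ~ " + " + ".join(parts)


def _coef_table(res) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )


def _fit(formula: str, df: pd.DataFrame, logistic: bool):
    if logistic:
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
    else:
        model = smf.ols(formula, data=df)
    X = model.exog if not hasattr(model, "data") else model.data.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            f"design matrix is rank-deficient ({rank} < {X.shape[1]}); "
            "check for collinear covariates"
        )
    res = model.fit()
    if logistic and not np.all(np.isfinite(res.bse)):
        raise ModelError("non-finite standard errors (possible separation)")
    return res


def cross_sectional_model(
    data: pd.DataFrame,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    adjust_first_visit_year: bool = True,
) -> AssociationResult:
    """Cross-sectional regression of a CHIP measure at the first visit.

    ``outcome`` is one of chip_prevalence / large_clone_prevalence (logistic on
    the corresponding indicator column) or log10_vaf (linear).  ``data`` holds
    one row per subject with the outcome column, covariates, and (optionally)
    first_visit_year.
    """
    if outcome in PREVALENCE_OUTCOMES:
        col, logistic = PREVALENCE_OUTCOMES[outcome], True
    elif outcome in CONTINUOUS_OUTCOMES:
        col, logistic = outcome, False
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    extra = ("first_visit_year",) if adjust_first_visit_year else ()
    needed = [col, *covariates, *extra]
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    usable = data.dropna(subset=needed)
    n_excluded = len(data) - len(usable)
    if n_excluded:
        logger.info("%s: excluded %d subjects with missing data", outcome, n_excluded)
    if len(usable) < len(covariates) + 2:
        raise ModelError(f"too few usable subjects ({len(usable)})")
    if logistic:
        usable = usable.assign(**{col: usable[col].astype(int)})
    _check_design(usable, [c for c in (*covariates, *extra)])
    res = _fit(_formula(col, covariates, extra), usable, logistic)
    return AssociationResult(
        outcome=outcome,
        model="logistic" if logistic else "linear",
        coefficients=_coef_table(res),
        n_used=len(usable),
        n_excluded_missing=n_excluded,
    )


def longitudinal_growth_model(
    deltas: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    adjust_first_visit_year: bool = True,
) -> AssociationResult:
    """Linear model of the dominant clone's Δlog10(VAF) on covariates.

    ``deltas`` holds one row per subject with delta_log10_vaf (last minus
    first non-zero VAF on the log10 scale), the covariates, and optionally
    first_visit_year.  Complete-case; requires ≥3 usable subjects.
    """
    extra = ("first_visit_year",) if adjust_first_visit_year else ()
    needed = ["delta_log10_vaf", *covariates, *extra]
    missing_cols = [c for c in needed if c not in deltas.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    usable = deltas.dropna(subset=needed)
    n_excluded = len(deltas) - len(usable)
    if n_excluded:
        logger.info("growth model: excluded %d subjects with missing data", n_excluded)
    if len(usable) < 3:
        raise ModelError(f"need at least 3 usable subjects (have {len(usable)})")
    _check_design(usable, [c for c in (*covariates, *extra)])
    res = _fit(_formula("delta_log10_vaf", covariates, extra), usable, logistic=False)
    return AssociationResult(
        outcome="delta_log10_vaf",
        model="linear",
        coefficients=_coef_table(res),
        n_used=len(usable),
        n_excluded_missing=n_excluded,
    )
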