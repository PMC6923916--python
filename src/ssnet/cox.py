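"""Cox proportional hazards fits for group effects and confounder checks.

The hazard ratio of group 1 vs group 2 quantifies how much worse survival
is for patients with a large ΔPCC of a pair; a multivariable fit with age
and gender lets the user check whether those demographics, rather than the
group split, explain the survival difference (a confounder would show an
HR away from 1 with a small p-value).

Fitting is by partial-likelihood maximization with the Efron tie
correction; 95% confidence intervals use the normal approximation on the
coefficient scale, exp(coef +/- 1.96 * se).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .types import SurvivalTable, ValidationError

GENDER_CODE = {"male": 0.0, "female": 1.0}  # documented convention: female = 1


@dataclass
class CoxFit:
    """Result of one Cox PH fit (one entry per covariate)."""

    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    p: np.ndarray
    ci95: list[tuple[float, float]]
    n_used: int
    n_dropped: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.coefficients,
            "hazard_ratio": self.hazard_ratios,
            "se": self.se,
            "p": self.p,
            "ci95_low": [lo for lo, _ in self.ci95],
            "ci95_high": [hi for _, hi in self.ci95],
        })

    def for_covariate(self, name: str) -> dict:
        i = self.covariates.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "hazard_ratio": float(self.hazard_ratios[i]),
            "se": float(self.se[i]),
            "p": float(self.p[i]),
            "ci95": self.ci95[i],
        }


def _failed_fit(names: list[str], n_used: int, n_dropped: int) -> CoxFit:
    k = len(names)
    nan = np.full(k, np.nan)
    return CoxFit(covariates=names, coefficients=nan, hazard_ratios=nan.copy(),
                  se=nan.copy(), p=nan.copy(), ci95=[(np.nan, np.nan)] * k,
                  n_used=n_used, n_dropped=n_dropped, converged=False)


def cox_fit(times: Sequence[float], events: Sequence[bool],
            covariates: pd.DataFrame) -> CoxFit:
    """Cox PH fit of ``times``/``events`` on the named covariate columns.

    Records with a missing covariate value are dropped (count reported in
    ``n_dropped``). Non-convergence or perfect separation yields a flagged
    fit with ``converged=False`` rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    names = [str(c) for c in covariates.columns]
    if not names:
        raise ValidationError("no covariates to fit")
    if len(times) != len(covariates) or len(events) != len(covariates):
        raise ValidationError("times/events/covariates length mismatch")

    keep = ~covariates.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    frame = covariates.loc[keep].astype(float).copy()
    frame["__time__"] = times[keep]
    frame["__event__"] = events[keep].astype(int)
    n_used = len(frame)

    if frame["__event__"].sum() < 2:
        raise ValidationError("Cox fit requires at least 2 events")
    for name in names:
        if frame[name].nunique() < 2:
            raise ValidationError(f"covariate {name!r} has zero variance")

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(frame, duration_col="__time__", event_col="__event__")
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    except ConvergenceError:
        return _failed_fit(names, n_used, n_dropped)

    coef = fitter.params_.reindex(names).to_numpy(dtype=float)
    se = fitter.standard_errors_.reindex(names).to_numpy(dtype=float)
    hr = np.exp(coef)
    ci = [(float(np.exp(c - 1.96 * s)), float(np.exp(c + 1.96 * s)))
          for c, s in zip(coef, se)]
    pvals = fitter.summary["p"].reindex(names).to_numpy(dtype=float)
    return CoxFit(covariates=names, coefficients=coef, hazard_ratios=hr, se=se,
                  p=pvals, ci95=ci, n_used=n_used, n_dropped=n_dropped,
                  converged=converged)


def group_hazard_ratio(survival: SurvivalTable, group1: set[str]) -> CoxFit:
    """Univariable Cox fit of the group-1 indicator (group 2 is baseline)."""
    indicator = pd.DataFrame(
        {"group1": [1.0 if s in group1 else 0.0 for s in survival.sample_ids]}
    )
    return cox_fit(survival.time, survival.event, indicator)


def confounder_check(survival: SurvivalTable, group1: set[str],
                     use_age: bool = True, use_gender: bool = True) -> CoxFit:
    """Multivariable Cox fit: group indicator plus available age/gender.

    Covariates that are absent from the table (or requested off) are
    silently omitted; an all-missing covariate is dropped with a warning.
    Gender is coded male=0, female=1.
    """
    data = {"group1": [1.0 if s in group1 else 0.0 for s in survival.sample_ids]}
    if use_age and survival.age is not None:
        if np.all(np.isnan(survival.age)):
            warnings.warn("age column entirely missing; dropped", stacklevel=2)
        else:
            data["age"] = survival.age
    if use_gender and survival.gender is not None:
        coded = [GENDER_CODE.get(g, np.nan) if g is not None else np.nan
                 for g in survival.gender]
        if np.all(np.isnan(coded)):
            warnings.warn("gender column entirely missing; dropped", stacklevel=2)
        else:
            data["gender"] = coded
    return cox_fit(survival.time, survival.event, pd.DataFrame(data))
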