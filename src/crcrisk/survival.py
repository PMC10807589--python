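"""Recurrence-free survival: Kaplan-Meier, log-rank and Cox PH.

Thin, validated wrappers around lifelines, returning plain pandas/dataclass
results so the rest of the pipeline never touches fitter objects. Cox ties
use the Efron approximation (lifelines' default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = ["km_estimate", "logrank_test", "CoxResult", "cox_fit", "SurvivalFit", "fit_survival"]


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a DataFrame with columns ``time``, ``at_risk``,
    ``events``, ``censored`` and ``survival`` (the step value just after
    ``time``).
    """
    t, e = _validate(times, events)
    if t.size == 0:
        raise ValueError("no observations")
    g = np.asarray(["all"] * len(t)) if groups is None else np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(g):
        mask = g == label
        if not mask.any():
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        tbl = kmf.event_table.reset_index().rename(
            columns={"event_at": "time", "at_risk": "at_risk", "observed": "events"}
        )
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        out[str(label)] = pd.DataFrame(
            {
                "time": tbl["time"].to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(dtype=int),
                "events": tbl["events"].to_numpy(dtype=int),
                "censored": tbl["censored"].to_numpy(dtype=int),
                "survival": surv,
            }
        )
    return out


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> tuple[float, float]:
    """Standard log-rank chi-square and p for two or more groups."""
    t, e = _validate(times, events)
    g = np.asarray(groups)
    if len(pd.unique(g)) < 2:
        raise ValueError("log-rank needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate Cox PH estimates with convergence diagnostics."""

    table: pd.DataFrame  # index covariate; columns log_hr, se, hr, p, ci_lower, ci_upper
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.table.loc[covariate]


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
) -> CoxResult:
    """Cox proportional hazards by partial likelihood (Efron ties).

    Separation / monotone-likelihood problems are surfaced as a flagged
    result (``converged=False`` plus captured warnings), never silently.
    """
    t, e = _validate(times, events)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    df = cov.copy()
    df["_time"] = t
    df["_event"] = e

    cph = CoxPHFitter()
    caught: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            return CoxResult(
                table=pd.DataFrame(
                    np.nan,
                    index=list(cov.columns),
                    columns=["log_hr", "se", "hr", "p", "ci_lower", "ci_upper"],
                ),
                converged=False,
                warnings=[str(exc)],
            )
        for w in wlist:
            msg = str(w.message)
            caught.append(msg)
            if "convergence" in msg.lower() or "monotone" in msg.lower() or "complete separation" in msg.lower():
                converged = False

    s = cph.summary
    table = pd.DataFrame(
        {
            "log_hr": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "p": s["p"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table, converged=converged, warnings=caught)


@dataclass
class SurvivalFit:
    """Bundle of KM curves, log-rank test and (optional) Cox fit."""

    km: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult | None = None


def fit_survival(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> SurvivalFit:
    """KM + log-rank for the grouping, plus Cox on covariates when given."""
    km = km_estimate(times, events, groups)
    chi2, p = logrank_test(times, events, groups)
    cox = cox_fit(times, events, covariates) if covariates is not None else None
    return SurvivalFit(km=km, logrank_chi2=chi2, logrank_p=p, cox=cox)
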