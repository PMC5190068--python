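"""Kaplan-Meier estimation, log-rank tests and Cox regression.

Endpoints are recurrence-free survival (event = recurrence) and overall
survival (event = death), both measured in days from the end of first-line
therapy.  Cox fits use the Efron approximation for tied event times.

The covariate coding of low/high status is left to the caller: fits report
hazard ratios for a unit increase of the covariate as supplied, and the
chosen reference level is recorded in the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .cohort import ExpressionCohort

log = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalOutcome:
    sample_id: str
    time: float
    event: bool
    endpoint: str = "recurrence"  # recurrence | overall

    def __post_init__(self):
        if self.time <= 0:
            raise SurvivalError(f"{self.sample_id}: time must be > 0")


@dataclass
class KMCurve:
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CovariateEffect:
    covariate: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    effects: list[CovariateEffect]
    ties_method: str
    converged: bool
    n_events: int
    mode: str  # univariate | multivariate
    warnings: list[str] = field(default_factory=list)


def outcomes_from_cohort(cohort: ExpressionCohort, endpoint: str = "recurrence") -> list[SurvivalOutcome]:
    """Build survival outcomes from clinical records.

    Recurrence endpoint: recurrent samples contribute their
    days_to_tumor_recurrence as events; non-recurrent samples are censored
    at days_to_last_followup (covariate) or days_to_death.  Overall
    endpoint: deceased samples are events at days_to_death.
    """
    out = []
    for s in cohort.samples:
        rec = cohort.clinical[s]
        if endpoint == "recurrence":
            if rec.recurrence_status == "recurrence":
                out.append(SurvivalOutcome(s, rec.days_to_tumor_recurrence, True, endpoint))
            elif rec.recurrence_status == "norecurrence":
                t = rec.covariates.get("days_to_last_followup", rec.days_to_death)
                if t is not None:
                    out.append(SurvivalOutcome(s, float(t), False, endpoint))
        elif endpoint == "overall":
            if rec.days_to_death is not None and rec.vital_status != "unknown":
                out.append(SurvivalOutcome(s, rec.days_to_death,
                                           rec.vital_status == "deceased", endpoint))
        else:
            raise SurvivalError(f"unknown endpoint {endpoint!r}")
    return out


def _frame(outcomes: Sequence[SurvivalOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in outcomes],
            "time": [o.time for o in outcomes],
            "event": [int(o.event) for o in outcomes],
        }
    ).set_index("sample_id")


def km_curve(outcomes: Sequence[SurvivalOutcome]) -> KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""
    df = _frame(outcomes)
    if df["event"].sum() == 0:
        raise SurvivalError("no events")
    kmf = KaplanMeierFitter().fit(df["time"], df["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    s = np.cumprod(1 - d / n)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    se = s * np.sqrt(gw)
    return KMCurve(
        times=ev.index.to_numpy(dtype=float),
        survival=s,
        greenwood_se=se,
        n_at_risk=n.astype(int),
    )


def logrank_test(outcomes: Sequence[SurvivalOutcome], groups: Sequence) -> LogrankResult:
    """Mantel-Haenszel log-rank comparison of >= 2 groups."""
    df = _frame(outcomes)
    g = np.asarray(groups)
    if len(g) != len(df):
        raise SurvivalError("groups length mismatch")
    if len(np.unique(g)) < 2:
        raise SurvivalError("need >= 2 groups")
    res = multivariate_logrank_test(df["time"].to_numpy(), g, df["event"].to_numpy())
    return LogrankResult(chi2=float(res.test_statistic),
                         df=int(res.degrees_of_freedom), p=float(res.p_value))


def cox_regression(
    outcomes: Sequence[SurvivalOutcome],
    covariates: pd.DataFrame,
    mode: str = "multivariate",
) -> list[CoxFit]:
    """Cox proportional-hazards fit(s) with Efron tie handling.

    ``covariates`` is indexed by sample_id.  Univariate mode fits each
    column alone and returns one fit per covariate; multivariate mode
    returns a single joint fit.  Perfect separation or non-convergence is
    flagged rather than silently accepted.
    """
    df = _frame(outcomes)
    cov = covariates.loc[df.index]
    if int(df["event"].sum()) < 10:
        raise SurvivalError("need >= 10 events")
    if (cov.nunique() <= 1).any():
        bad = cov.columns[cov.nunique() <= 1].tolist()
        raise SurvivalError(f"constant covariate(s): {bad}")
    if mode == "univariate":
        return [
            _fit_one(df, cov[[col]], "univariate") for col in cov.columns
        ]
    if mode != "multivariate":
        raise SurvivalError(f"unknown mode {mode!r}")
    return [_fit_one(df, cov, "multivariate")]


def _fit_one(df: pd.DataFrame, cov: pd.DataFrame, mode: str) -> CoxFit:
    data = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    warnings_: list[str] = []
    converged = True
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        log.warning("Cox fit failed to converge: %s", exc)
        return CoxFit(effects=[], ties_method="efron", converged=False,
                      n_events=int(df["event"].sum()), mode=mode,
                      warnings=[str(exc)])
    summary = cph.summary
    effects = []
    for name, row in summary.iterrows():
        if abs(row["coef"]) > 20:
            warnings_.append(f"{name}: infinite-coefficient warning (possible separation)")
        effects.append(
            CovariateEffect(
                covariate=str(name),
                beta=float(row["coef"]),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
            )
        )
    return CoxFit(effects=effects, ties_method="efron", converged=converged,
                  n_events=int(df["event"].sum()), mode=mode, warnings=warnings_)


def km_frame(curve: KMCurve) -> pd.DataFrame:
    """Export a KM curve as a (time, S, se, at_risk) table."""
    return pd.DataFrame(
        {"time": curve.times, "S": curve.survival,
         "se": curve.greenwood_se, "at_risk": curve.n_at_risk}
    )
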