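"""Right-censored survival estimation and testing.

Kaplan–Meier product-limit curves with Greenwood variance, median survival
with Brookmeyer–Crowley style confidence intervals, reverse-KM median
follow-up, the (unweighted) log-rank test and multivariate Cox proportional
hazards with the Efron tie correction. Estimation is delegated to lifelines;
this module fixes the conventions used throughout the package (months,
event = 1 / censored = 0, log-log confidence bands by default) and exposes
typed result containers.

``NOT_REACHED`` (``inf``) marks a median or CI bound the curve never
attains; reports render it as ``"NR"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

NOT_REACHED = float("inf")


def fmt_months(value: float) -> str:
    """Render a time in months, with NR for a value never reached."""
    return "NR" if np.isinf(value) else f"{value:g}"


@dataclass
class SurvivalCurve:
    """A Kaplan–Meier step function with its risk table.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``greenwood_var``
    is Greenwood's variance estimate of S at the same points.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    n_events: int
    ci_method: str = "log-log"
    _kmf: KaplanMeierFitter | None = field(default=None, repr=False, compare=False)

    def survival_at(self, t: float) -> float:
        """S(t): the step value at the last event time <= t (1 before any)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        """Risk table with S(t) and its confidence band, one row per event time."""
        lower, upper = self.confidence_band()
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
            "ci_lower": lower,
            "ci_upper": upper,
        })

    def confidence_band(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI for S at each event time (log-log or linear Greenwood)."""
        z = stats.norm.ppf(1 - alpha / 2)
        s = self.survival
        if self.ci_method == "linear":
            half = z * np.sqrt(self.greenwood_var)
            return np.clip(s - half, 0, 1), np.clip(s + half, 0, 1)
        # complementary log-log ("exponential Greenwood") transform
        lower = np.zeros_like(s)
        upper = np.ones_like(s)
        interior = (s > 0) & (s < 1)
        si = s[interior]
        se_cll = np.sqrt(self.greenwood_var[interior]) / np.abs(si * np.log(si))
        lower[interior] = si ** np.exp(z * se_cll)
        upper[interior] = si ** np.exp(-z * se_cll)
        lower[s == 0] = 0.0
        upper[s == 0] = 0.0
        return lower, upper


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival time with 95% CI; ``inf`` encodes NR/not estimable."""

    median: float
    ci_lower: float
    ci_upper: float

    def __str__(self) -> str:  # e.g. "4.5 (95% CI: 3.4-6.9)"
        return (f"{fmt_months(self.median)} "
                f"(95% CI: {fmt_months(self.ci_lower)}-{fmt_months(self.ci_upper)})")


def _validate(times: Sequence[float], events: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


def kaplan_meier(
    times: Sequence[float],
    events: Sequence[int],
    ci_method: str = "log-log",
) -> SurvivalCurve:
    """Product-limit estimate of S(t) under right censoring.

    Ties at one time are resolved events-first (the standard risk-set
    convention). An all-censored input is legal and yields S ≡ 1 with no
    event times.
    """
    t, e = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    observed = table["observed"].to_numpy()
    mask = observed > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=int)[mask]
    d = observed[mask].astype(int)
    surv = np.array([kmf.predict(x) for x in event_times], dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_k <= t} d_k / (n_k (n_k - d_k))
    with np.errstate(divide="ignore"):
        increments = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
    gvar = surv**2 * np.cumsum(increments)
    gvar = np.where(np.isfinite(gvar), gvar, 0.0)  # S=0 endpoint: variance 0
    return SurvivalCurve(
        event_times=event_times, at_risk=at_risk, events=d, survival=surv,
        greenwood_var=gvar, n_total=int(t.size), n_events=int(e.sum()),
        ci_method=ci_method, _kmf=kmf,
    )


def median_survival(curve: SurvivalCurve) -> MedianEstimate:
    """Median = smallest event time with S(t) <= 0.5; NR when never attained.

    The CI is read off where the pointwise confidence band of S crosses 0.5
    (Brookmeyer–Crowley construction on the configured band transform).
    """
    below = np.nonzero(curve.survival <= 0.5)[0]
    med = float(curve.event_times[below[0]]) if below.size else NOT_REACHED
    lower, upper = curve.confidence_band()
    # the lower band of S crosses 0.5 earliest -> lower bound of the median CI
    lo_idx = np.nonzero(lower <= 0.5)[0]
    hi_idx = np.nonzero(upper <= 0.5)[0]
    ci_lower = float(curve.event_times[lo_idx[0]]) if lo_idx.size else NOT_REACHED
    ci_upper = float(curve.event_times[hi_idx[0]]) if hi_idx.size else NOT_REACHED
    return MedianEstimate(median=med, ci_lower=ci_lower, ci_upper=ci_upper)


def reverse_km_followup(times: Sequence[float], events: Sequence[int]) -> MedianEstimate:
    """Median follow-up by the reverse Kaplan–Meier method.

    Complements the event indicator (censoring becomes the event of
    interest, deaths are censored) and returns the median of that curve.
    """
    t, e = _validate(times, events)
    return median_survival(kaplan_meier(t, 1 - e))


@dataclass(frozen=True)
class LogRankResult:
    """Unweighted log-rank test over pooled event times."""

    statistic: float
    df: int
    p_value: float

    def p_display(self, floor: float = 1e-4) -> str:
        return f"< {floor:g}" if self.p_value < floor else f"{self.p_value:.4g}"


def log_rank(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> LogRankResult:
    """Compare K >= 2 survival distributions; chi-square on K−1 df."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t, e = np.asarray(t, float), np.asarray(e, int)
        if t.size == 0:
            raise ValueError(f"log-rank group {i} has zero observations")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events))
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(groups) - 1, p_value=float(res.p_value))


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate: coef, hr, ci_lower, ci_upper, se,
    p (Wald). HR = exp(coef); CI bounds = exp(coef ± 1.96·SE).
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    diagnostics: str = ""


def cox_ph(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
) -> CoxFit:
    """Fit a multivariate Cox model (Efron tie correction, Newton ascent).

    ``covariates`` holds binary/continuous columns with no missing values.
    Non-convergence or monotone-likelihood separation is reported via the
    ``converged`` flag and ``diagnostics``, never silently.
    """
    t, e = _validate(times, events)
    if e.sum() < 1:
        raise ValueError("Cox model requires at least one observed event")
    if covariates.isna().any().any():
        raise ValueError("Cox covariates must not contain missing values")
    frame = covariates.reset_index(drop=True).astype(float).copy()
    frame["_time"] = t
    frame["_event"] = e
    cph = CoxPHFitter()
    converged, notes = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(frame, duration_col="_time", event_col="_event")
        except Exception as exc:  # convergence / separation failures
            return CoxFit(summary=pd.DataFrame(), log_likelihood=float("nan"),
                          converged=False, n=int(t.size), n_events=int(e.sum()),
                          diagnostics=f"fit failed: {exc}")
        messages = [str(w.message) for w in caught]
        suspect = [m for m in messages if "convergence" in m.lower()
                   or "separation" in m.lower() or "collinear" in m.lower()]
        if suspect:
            converged = False
            notes = "; ".join(suspect)
    if np.any(np.abs(cph.params_.to_numpy()) > 20):
        converged = False
        notes = (notes + "; " if notes else "") + \
            "coefficient diverged beyond bound (possible monotone likelihood)"
    raw = cph.summary
    summary = pd.DataFrame({
        "coef": raw["coef"],
        "hr": raw["exp(coef)"],
        "ci_lower": raw["exp(coef) lower 95%"],
        "ci_upper": raw["exp(coef) upper 95%"],
        "se": raw["se(coef)"],
        "p": raw["p"],
    })
    summary.index.name = "covariate"
    return CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_),
                  converged=converged, n=int(t.size), n_events=int(e.sum()),
                  diagnostics=notes)
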