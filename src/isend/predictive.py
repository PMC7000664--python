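"""Time-dependent PPV/NPV of binary prognostic markers under right censoring.

Estimand. For a marker oriented toward the event (e.g. the iSEND Poor
group, or PD-L1 = 0%), the time-dependent positive predictive value is

    PPV(t) = P(event <= t | marker positive) = 1 - S_pos(t),

where S_pos is the Kaplan–Meier curve restricted to marker-positive
patients. For a marker oriented toward survival (iSEND Good, PD-L1 >= 50%)
the negative predictive value is NPV(t) = S_marker(t). With no censoring
before t these reduce to the naive within-group proportions. Confidence
intervals come from the log-log (exponential Greenwood) band of the
within-group curve, complemented for PPV.

Marker comparison. Two markers on the same cohort are compared at a fixed
horizon by a paired nonparametric bootstrap: patients are resampled with
replacement, both predictive values recomputed each replicate, and the
observed difference tested against the bootstrap standard error with a
two-sided normal (Wald) test. Pairing makes the test valid when the marker
groups overlap. An independent two-proportion z-test on the Greenwood
standard errors is available as a sensitivity alternative.

The product-limit evaluation here is a self-contained vectorised
implementation (events-first tie handling, identical to the grouped
estimator) so that bootstrap loops stay fast; it is cross-checked against
the curve-based estimator in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class BinaryMarker:
    """A named binary patient classifier.

    ``positive`` maps a cohort DataFrame to a boolean mask selecting
    marker-positive patients. ``orientation`` says whether positivity
    predicts the event (PPV semantics) or survival (NPV semantics).
    """

    name: str
    positive: Callable[[pd.DataFrame], pd.Series]
    orientation: str = "predicts_event"


def isend_group_marker(group: str) -> BinaryMarker:
    """Marker 'iSEND group == {good|intermediate|poor}' (column isend_group)."""
    orientation = "predicts_survival" if group == "good" else "predicts_event"
    return BinaryMarker(name=f"isend_{group}",
                        positive=lambda df: df["isend_group"] == group,
                        orientation=orientation)


def pdl1_marker(category: str) -> BinaryMarker:
    """Marker 'PD-L1 category == {p0|p1_49|p50plus}'."""
    orientation = "predicts_survival" if category == "p50plus" else "predicts_event"
    return BinaryMarker(name=f"pdl1_{category}",
                        positive=lambda df: df["pdl1"] == category,
                        orientation=orientation)


# ---------------------------------------------------------------------------
# fast product-limit evaluation at a single horizon


def km_at_horizon(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> tuple[float, float]:
    """(S(t), Greenwood variance of S(t)) at a single horizon.

    Processes tied events one at a time; the running products/sums collapse
    algebraically to the grouped Kaplan–Meier and Greenwood formulas.
    """
    order = np.lexsort((1 - events, times))  # time asc, events before censorings
    t = times[order]
    e = events[order]
    n = t.size
    at_risk = n - np.arange(n)
    mask = (e == 1) & (t <= horizon)
    r = at_risk[mask].astype(float)
    s = float(np.prod(1.0 - 1.0 / r))
    with np.errstate(divide="ignore"):
        gsum = float(np.sum(np.where(r > 1, 1.0 / (r * (r - 1.0)), np.inf)))
    var = s * s * gsum if np.isfinite(gsum) else 0.0  # S hit 0: variance 0
    return s, var


def _loglog_band(s: float, var: float) -> tuple[float, float]:
    """95% log-log CI for a survival probability with Greenwood variance."""
    if s <= 0.0:
        return 0.0, 0.0
    if s >= 1.0 or var <= 0.0:
        return s, s
    se_cll = np.sqrt(var) / abs(s * np.log(s))
    return float(s ** np.exp(_Z95 * se_cll)), float(s ** np.exp(-_Z95 * se_cll))


@dataclass(frozen=True)
class PredictiveValueEstimate:
    """PPV or NPV at a fixed horizon, with 95% CI and the group size."""

    marker: str
    horizon: float
    kind: str  # "ppv" | "npv"
    value: float | None
    ci_lower: float | None
    ci_upper: float | None
    n_group: int
    estimable: bool = True
    reason: str | None = None

    @staticmethod
    def not_estimable(marker: str, horizon: float, kind: str,
                      n_group: int, reason: str) -> "PredictiveValueEstimate":
        return PredictiveValueEstimate(marker=marker, horizon=horizon, kind=kind,
                                       value=None, ci_lower=None, ci_upper=None,
                                       n_group=n_group, estimable=False, reason=reason)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    return f"{endpoint}_time", f"{endpoint}_event"


def _group_arrays(cohort: pd.DataFrame, marker: BinaryMarker,
                  endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(marker.positive(cohort), dtype=bool)
    tcol, ecol = _endpoint_columns(endpoint)
    sub = cohort.loc[mask, [tcol, ecol]].dropna()
    return sub[tcol].to_numpy(dtype=float), sub[ecol].to_numpy(dtype=int)


def time_dependent_ppv(
    cohort: pd.DataFrame,
    marker: BinaryMarker,
    horizon: float,
    endpoint: str = "os",
) -> PredictiveValueEstimate:
    """PPV(t) = 1 − S_KM(t) within the marker-positive subgroup.

    Returns a NOT-ESTIMABLE result (never raises) when the positive group is
    empty or nobody is still at risk at the horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t, e = _group_arrays(cohort, marker, endpoint)
    if t.size == 0:
        return PredictiveValueEstimate.not_estimable(
            marker.name, horizon, "ppv", 0, "empty marker-positive group")
    if not _at_risk_ok(t, e, horizon):
        return PredictiveValueEstimate.not_estimable(
            marker.name, horizon, "ppv", int(t.size),
            "no patients at risk at the horizon")
    s, var = km_at_horizon(t, e, horizon)
    lo_s, hi_s = _loglog_band(s, var)
    return PredictiveValueEstimate(
        marker=marker.name, horizon=horizon, kind="ppv",
        value=1.0 - s, ci_lower=1.0 - hi_s, ci_upper=1.0 - lo_s,
        n_group=int(t.size))


def time_dependent_npv(
    cohort: pd.DataFrame,
    marker: BinaryMarker,
    horizon: float,
    endpoint: str = "os",
) -> PredictiveValueEstimate:
    """NPV(t) = S_KM(t) within the group the marker flags as good-outcome."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t, e = _group_arrays(cohort, marker, endpoint)
    if t.size == 0:
        return PredictiveValueEstimate.not_estimable(
            marker.name, horizon, "npv", 0, "empty marker group")
    if not _at_risk_ok(t, e, horizon):
        return PredictiveValueEstimate.not_estimable(
            marker.name, horizon, "npv", int(t.size),
            "no patients at risk at the horizon")
    s, var = km_at_horizon(t, e, horizon)
    lo_s, hi_s = _loglog_band(s, var)
    return PredictiveValueEstimate(
        marker=marker.name, horizon=horizon, kind="npv",
        value=s, ci_lower=lo_s, ci_upper=hi_s, n_group=int(t.size))


def _at_risk_ok(t: np.ndarray, e: np.ndarray, horizon: float) -> bool:
    # estimable iff someone is still under observation at the horizon, or the
    # curve is already fully determined (everyone had the event) before it
    if np.any(t >= horizon):
        return True
    return bool(np.all(e == 1))


@dataclass(frozen=True)
class MarkerComparison:
    """Paired comparison of two predictive values at one horizon."""

    horizon: float
    kind: str
    estimate_a: PredictiveValueEstimate
    estimate_b: PredictiveValueEstimate
    difference: float | None
    p_value: float | None
    method: str
    n_bootstrap: int | None = None
    seed: int | None = None
    estimable: bool = True
    reason: str | None = None


def _point_value(t: np.ndarray, e: np.ndarray, horizon: float, kind: str) -> float:
    s, _ = km_at_horizon(t, e, horizon)
    return 1.0 - s if kind == "ppv" else s


def compare_markers(
    cohort: pd.DataFrame,
    marker_a: BinaryMarker,
    marker_b: BinaryMarker,
    horizon: float,
    endpoint: str = "os",
    kind: str = "ppv",
    B: int = 2000,
    seed: int = 0,
    method: str = "paired_bootstrap",
) -> MarkerComparison:
    """Test PPV_a(t) = PPV_b(t) (or NPV) on a shared cohort.

    ``paired_bootstrap`` (default): resample patients with replacement B
    times, recompute both values per replicate; two-sided Wald p against the
    bootstrap SE of the difference. Replicates where either marker group is
    empty or not at risk are redrawn, capped at 10·B attempts.
    ``independent_z``: normal z-test treating the two groups' Greenwood
    variances as independent (sensitivity alternative).
    """
    if kind not in ("ppv", "npv"):
        raise ValueError("kind must be 'ppv' or 'npv'")
    estimator = time_dependent_ppv if kind == "ppv" else time_dependent_npv
    est_a = estimator(cohort, marker_a, horizon, endpoint)
    est_b = estimator(cohort, marker_b, horizon, endpoint)
    if not (est_a.estimable and est_b.estimable):
        bad = est_a if not est_a.estimable else est_b
        return MarkerComparison(horizon=horizon, kind=kind, estimate_a=est_a,
                                estimate_b=est_b, difference=None, p_value=None,
                                method=method, estimable=False, reason=bad.reason)
    diff = est_a.value - est_b.value

    if method == "independent_z":
        ta, ea = _group_arrays(cohort, marker_a, endpoint)
        tb, eb = _group_arrays(cohort, marker_b, endpoint)
        _, va = km_at_horizon(ta, ea, horizon)
        _, vb = km_at_horizon(tb, eb, horizon)
        se = float(np.sqrt(va + vb))
        p = 1.0 if se == 0 and diff == 0 else \
            2.0 * stats.norm.sf(abs(diff) / se) if se > 0 else 0.0
        return MarkerComparison(horizon=horizon, kind=kind, estimate_a=est_a,
                                estimate_b=est_b, difference=diff, p_value=p,
                                method="independent_z")

    if method != "paired_bootstrap":
        raise ValueError(f"unknown method {method!r}")

    tcol, ecol = _endpoint_columns(endpoint)
    sub = cohort.dropna(subset=[tcol, ecol])
    times = sub[tcol].to_numpy(dtype=float)
    events = sub[ecol].to_numpy(dtype=int)
    mask_a = np.asarray(marker_a.positive(sub), dtype=bool)
    mask_b = np.asarray(marker_b.positive(sub), dtype=bool)
    n = times.size
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    attempts = 0
    filled = 0
    max_attempts = 10 * B
    while filled < B and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        ia = idx[mask_a[idx]]
        ib = idx[mask_b[idx]]
        if ia.size == 0 or ib.size == 0:
            continue
        ta, ea = times[ia], events[ia]
        tb, eb = times[ib], events[ib]
        if not (_at_risk_ok(ta, ea, horizon) and _at_risk_ok(tb, eb, horizon)):
            continue
        diffs[filled] = (_point_value(ta, ea, horizon, kind)
                         - _point_value(tb, eb, horizon, kind))
        filled += 1
    if filled < B:
        return MarkerComparison(horizon=horizon, kind=kind, estimate_a=est_a,
                                estimate_b=est_b, difference=diff, p_value=None,
                                method=method, n_bootstrap=filled, seed=seed,
                                estimable=False,
                                reason="bootstrap replicates repeatedly degenerate")
    se = float(np.std(diffs, ddof=1))
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(diff) / se))
    return MarkerComparison(horizon=horizon, kind=kind, estimate_a=est_a,
                            estimate_b=est_b, difference=diff, p_value=p,
                            method=method, n_bootstrap=B, seed=seed)
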