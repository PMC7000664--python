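"""End-to-end analysis orchestration: exclusions → scoring → survival →
predictive-value comparisons → cohort table → sex×smoking subgroups.

`run_full_analysis` produces an in-memory report bundle (dict of DataFrames
and records) and can write it to disk as CSV/JSON with a plain-text run
log. Re-running with identical inputs, config and seeds yields identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PatientRecord, apply_exclusions, records_to_frame
from .predictive import (
    BinaryMarker,
    compare_markers,
    isend_group_marker,
    pdl1_marker,
)
from .score import assign_groups
from .survival import (
    NOT_REACHED,
    cox_ph,
    kaplan_meier,
    log_rank,
    median_survival,
    reverse_km_followup,
)
from .tables import build_table1

SUBGROUP_ORDER = (
    ("female", "any"),
    ("male", "any"),
    ("female", "never"),
    ("male", "never"),
)


@dataclass
class AnalysisConfig:
    """Knobs for a full pipeline run."""

    endpoints: tuple[str, ...] = ("os", "pfs")
    horizons: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    bootstrap_B: int = 2000
    seed: int = 0
    #: (marker-a group, marker-b PD-L1 category, ppv|npv)
    comparisons: tuple[tuple[str, str, str], ...] = (
        ("poor", "p0", "ppv"),
        ("good", "p50plus", "npv"),
    )
    output_dir: str | None = None
    report_formats: tuple[str, ...] = ("csv", "json")
    exempt_chemo_from_nlr2: bool = False

    def validate(self) -> None:
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")
        if list(self.horizons) != sorted(set(self.horizons)):
            raise ValueError("horizons must be strictly increasing")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        for ep in self.endpoints:
            if ep not in ("os", "pfs"):
                raise ValueError(f"unknown endpoint {ep!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _scored_frame(records: Sequence[PatientRecord]):
    results, summary = assign_groups(records)
    frame = records_to_frame(records)
    frame["isend_score"] = [r.score for r in results]
    frame["isend_group"] = [r.group for r in results]
    frame["dnlr"] = frame["nlr2"] - frame["nlr1"]
    return frame, summary


def _km_by_group(frame: pd.DataFrame, group_col: str, endpoint: str,
                 group_order: Sequence[str]) -> tuple[pd.DataFrame, float]:
    """Per-group KM medians plus the overall log-rank p."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    rows = []
    groups = []
    for g in group_order:
        sub = frame[frame[group_col] == g].dropna(subset=[tcol, ecol])
        if len(sub) == 0:
            rows.append({"group": g, "n": 0, "events": 0,
                         "median": np.nan, "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        t = sub[tcol].to_numpy(float)
        e = sub[ecol].to_numpy(int)
        curve = kaplan_meier(t, e)
        med = median_survival(curve)
        rows.append({"group": g, "n": len(sub), "events": int(e.sum()),
                     "median": med.median, "ci_lower": med.ci_lower,
                     "ci_upper": med.ci_upper})
        groups.append((t, e))
    p = log_rank(groups).p_value if len(groups) >= 2 else np.nan
    return pd.DataFrame(rows), p


def subgroup_analysis(frame: pd.DataFrame, endpoint: str = "pfs"
                      ) -> tuple[pd.DataFrame, float]:
    """Sex × smoking-history subgroups (unknown smoking excluded).

    Order: female/smoker, male/smoker, female/never, male/never. Empty
    subgroups are reported with n = 0 and dropped from the log-rank test
    (df shrinks accordingly).
    """
    known = frame[frame["smoking"] != "unknown"].copy()
    known["subgroup"] = known["sex"] + "_" + known["smoking"]
    order = [f"{sex}_{smoke}" for sex, smoke in SUBGROUP_ORDER]
    return _km_by_group(known, "subgroup", endpoint, order)


def run_full_analysis(
    records: Sequence[PatientRecord],
    config: AnalysisConfig | None = None,
) -> dict:
    """Execute the whole analysis and return the report bundle.

    Bundle sections: ``exclusions``, ``group_sizes``, ``survival`` (KM
    medians + log-rank per endpoint per cohort label), ``followup``,
    ``cox`` (sex / ECOG>=2 / composite covariates, per cohort),
    ``ppv_comparisons`` (restricted to PD-L1-available patients),
    ``table1``, ``subgroups``, ``run_log``.
    """
    config = config or AnalysisConfig()
    config.validate()

    analysis_set, tally = apply_exclusions(
        list(records), exempt_chemo_from_nlr2=config.exempt_chemo_from_nlr2)
    if not analysis_set:
        raise PipelineError("exclusions", "analysis set is empty")

    try:
        frame, summary = _scored_frame(analysis_set)
    except ValueError as exc:
        raise PipelineError("scoring", str(exc)) from exc

    immuno = frame[frame["treatment"] == "pd1_mono"]
    cohort_views = {}
    if len(immuno):
        cohort_views["pooled"] = immuno
        for label in ("training", "validation"):
            sub = immuno[immuno["cohort"] == label]
            if len(sub):
                cohort_views[label] = sub
    chemo = frame[frame["treatment"] == "chemo_only"]
    if len(chemo):
        cohort_views["chemo"] = chemo

    survival_section = {}
    for label, view in cohort_views.items():
        for endpoint in config.endpoints:
            medians, p = _km_by_group(view, "isend_group", endpoint,
                                      ("good", "intermediate", "poor"))
            survival_section[f"{label}_{endpoint}"] = {
                "medians": medians, "log_rank_p": p}

    fu_frame = immuno if len(immuno) else frame
    fu = reverse_km_followup(fu_frame["os_time"].to_numpy(float),
                             fu_frame["os_event"].to_numpy(int))
    followup = {"median": fu.median, "ci_lower": fu.ci_lower, "ci_upper": fu.ci_upper}

    cox_section = {}
    for label, view in cohort_views.items():
        if label == "chemo" or len(view) < 10 or view["os_event"].sum() < 3:
            continue
        X = pd.DataFrame({
            "male": (view["sex"] == "male").astype(float),
            "ecog_2plus": (view["ecog"] >= 2).astype(float),
            "composite": ((view["nlr1"] >= 5) & (view["dnlr"] >= 0)).astype(float),
        })
        try:
            cox_section[label] = cox_ph(X, view["os_time"].to_numpy(float),
                                        view["os_event"].to_numpy(int))
        except ValueError as exc:
            raise PipelineError("cox", f"cohort {label}: {exc}") from exc

    pdl1_available = immuno[immuno["pdl1"] != "unknown"]
    comparisons = []
    for group, category, kind in config.comparisons:
        for horizon in config.horizons:
            if len(pdl1_available) == 0:
                comparisons.append({
                    "marker_a": f"isend_{group}", "marker_b": f"pdl1_{category}",
                    "kind": kind, "horizon": horizon, "estimable": False,
                    "reason": "no PD-L1-available patients",
                    "value_a": np.nan, "value_b": np.nan,
                    "difference": np.nan, "p_value": np.nan,
                })
                continue
            cmp = compare_markers(
                pdl1_available, isend_group_marker(group), pdl1_marker(category),
                horizon=horizon, endpoint="os", kind=kind,
                B=config.bootstrap_B, seed=config.seed)
            comparisons.append({
                "marker_a": cmp.estimate_a.marker, "marker_b": cmp.estimate_b.marker,
                "kind": kind, "horizon": horizon, "estimable": cmp.estimable,
                "reason": cmp.reason,
                "value_a": cmp.estimate_a.value, "value_b": cmp.estimate_b.value,
                "ci_a": (cmp.estimate_a.ci_lower, cmp.estimate_a.ci_upper),
                "ci_b": (cmp.estimate_b.ci_lower, cmp.estimate_b.ci_upper),
                "difference": cmp.difference, "p_value": cmp.p_value,
            })
    ppv_section = pd.DataFrame(comparisons)

    table1 = build_table1(
        [r for r in analysis_set if r.cohort in ("training", "validation")])

    sub_medians, sub_p = subgroup_analysis(
        immuno if len(immuno) else frame, endpoint="pfs")

    run_log = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bootstrap_B": config.bootstrap_B,
        "n_input": len(records),
        "n_analysis": len(analysis_set),
        "exclusions": dict(tally),
        "group_counts": summary.counts,
    }

    bundle = {
        "exclusions": tally,
        "group_sizes": summary,
        "survival": survival_section,
        "followup": followup,
        "cox": cox_section,
        "ppv_comparisons": ppv_section,
        "table1": table1,
        "subgroups": {"medians": sub_medians, "log_rank_p": sub_p},
        "run_log": run_log,
        "scored_frame": frame,
    }
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def _jsonable(value):
    if isinstance(value, float) and value == NOT_REACHED:
        return "NR"
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_bundle(bundle: dict, output_dir: str | Path) -> None:
    """Write the report bundle as CSVs plus a JSON summary and run log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, section in bundle["survival"].items():
        section["medians"].to_csv(out / f"km_medians_{key}.csv", index=False)
    for label, fit in bundle["cox"].items():
        fit.summary.to_csv(out / f"cox_{label}.csv")
    bundle["ppv_comparisons"].to_csv(out / "ppv_comparison.csv", index=False)
    bundle["table1"].rows.to_csv(out / "table1.csv", index=False)
    bundle["subgroups"]["medians"].to_csv(out / "subgroups.csv", index=False)
    summary = {
        "exclusions": dict(bundle["exclusions"]),
        "group_counts": bundle["group_sizes"].counts,
        "group_percentages": bundle["group_sizes"].percentages,
        "followup": {k: _jsonable(v) for k, v in bundle["followup"].items()},
        "log_rank_p": {key: _jsonable(section["log_rank_p"])
                       for key, section in bundle["survival"].items()},
        "subgroup_log_rank_p": _jsonable(bundle["subgroups"]["log_rank_p"]),
        "run_log": bundle["run_log"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable))
    log_lines = [f"{k}: {v}" for k, v in bundle["run_log"].items()]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
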