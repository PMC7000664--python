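"""Cohort-comparison statistics: Pearson chi-square, Wilcoxon rank-sum,
and the demographic/haematologic comparison table builder.

Conventions fixed here (they matter for reproducing published cohort
tables): Pearson chi-square without continuity correction; "Unknown"
categories shown in the table but excluded from the test; rank-sum p-values
exact for small tie-free samples, otherwise tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord, derive_haematology


@dataclass
class ContingencyTable:
    """An r x c count table with labelled margins."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    excluded_categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns after exclusions")


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value; df only for chi-square."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square test of row/column independence.

    Expected counts are products of margins over the grand total; df =
    (r−1)(c−1); p from the chi-square upper tail. A zero margin is an error
    naming the degenerate category.
    """
    counts = table.counts
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    for label, margin in zip(table.row_labels, row_margins):
        if margin == 0:
            raise ValueError(f"degenerate row category {label!r}: zero margin")
    for label, margin in zip(table.col_labels, col_margins):
        if margin == 0:
            raise ValueError(f"degenerate column category {label!r}: zero margin")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p),
                      method="pearson_chi_square", df=int(df))


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Mid-ranks for ties; exact null distribution when both samples are small
    and tie-free, otherwise the tie-corrected normal approximation with
    continuity correction. The statistic reported is the rank sum of the
    first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="auto")
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return TestResult(statistic=rank_sum, p_value=float(res.pvalue),
                      method="wilcoxon_rank_sum")


# ---------------------------------------------------------------------------
# cohort-comparison table

CATEGORICAL_VARIABLES: dict[str, dict] = {
    "sex": {"levels": ["male", "female"], "exclude": []},
    "smoking": {"levels": ["unknown", "any", "never"], "exclude": ["unknown"]},
    "ecog": {"levels": ["ecog_0_1", "ecog_2_3"], "exclude": []},
    "histology": {"levels": ["squamous", "non_squamous"], "exclude": []},
    "egfr_alk": {"levels": ["unknown", "no", "yes"], "exclude": ["unknown"]},
    "composite": {"levels": ["others", "composite"], "exclude": []},
}

CONTINUOUS_VARIABLES = ("age", "prior_lines", "nlr1", "dnlr")


def _categorise(records: Sequence[PatientRecord], variable: str) -> list[str]:
    if variable == "ecog":
        return ["ecog_0_1" if r.ecog < 2 else "ecog_2_3" for r in records]
    if variable == "composite":
        out = []
        for r in records:
            flag = derive_haematology(r).composite_flag if (
                r.nlr1 is not None and r.nlr2 is not None) else 0
            out.append("composite" if flag else "others")
        return out
    return [getattr(r, variable) for r in records]


def _continuous_values(records: Sequence[PatientRecord], variable: str) -> np.ndarray:
    if variable == "dnlr":
        vals = [derive_haematology(r).dnlr for r in records
                if r.nlr1 is not None and r.nlr2 is not None]
    else:
        vals = [getattr(r, variable) for r in records if getattr(r, variable) is not None]
    return np.asarray(vals, dtype=float)


@dataclass
class Table1Report:
    """Cohort-comparison table: per-variable rows plus a p-value column."""

    rows: pd.DataFrame
    tested: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def p_values(self) -> dict[str, float]:
        mask = self.rows["p_value"].notna()
        return dict(zip(self.rows.loc[mask, "variable"], self.rows.loc[mask, "p_value"]))

    def to_markdown(self) -> str:
        return self.rows.to_markdown(index=False)


def build_table1(
    cohort: Sequence[PatientRecord],
    percent_decimals: int = 1,
) -> Table1Report:
    """Build the demographic/haematologic comparison table.

    Categorical variables get counts and percentages per cohort label plus a
    pooled column, with a training-vs-validation chi-square p (Unknown
    levels displayed but excluded from the test). Continuous variables get
    median (range) and a rank-sum p. A single-cohort input produces the
    pooled column only, with no tests.
    """
    records = list(cohort)
    labels = sorted({r.cohort for r in records if r.cohort in ("training", "validation")})
    tested = len(labels) == 2 and all(
        any(r.cohort == lab for r in records) for lab in ("training", "validation"))
    by_cohort = {lab: [r for r in records if r.cohort == lab] for lab in labels}
    warnings: list[str] = []
    out_rows: list[dict] = []

    for variable, layout in CATEGORICAL_VARIABLES.items():
        levels, excluded = layout["levels"], layout["exclude"]
        pooled_cats = _categorise(records, variable)
        p_value = np.nan
        if tested:
            counts = np.array([
                [sum(c == lev for c in _categorise(by_cohort[lab], variable))
                 for lab in ("training", "validation")]
                for lev in levels if lev not in excluded
            ], dtype=float)
            keep_rows = [lev for lev in levels if lev not in excluded]
            try:
                table = ContingencyTable(row_labels=keep_rows,
                                         col_labels=["training", "validation"],
                                         counts=counts, excluded_categories=excluded)
                p_value = pearson_chi_square(table).p_value
            except ValueError as exc:
                warnings.append(f"{variable}: test skipped ({exc})")
        for i, lev in enumerate(levels):
            row = {"variable": variable, "level": lev,
                   "p_value": p_value if i == 0 else np.nan}
            n_pool = sum(c == lev for c in pooled_cats)
            row["pooled_n"] = n_pool
            row["pooled_pct"] = round(100.0 * n_pool / len(records), percent_decimals) \
                if records else 0.0
            for lab in labels:
                cats = _categorise(by_cohort[lab], variable)
                n_lab = sum(c == lev for c in cats)
                row[f"{lab}_n"] = n_lab
                row[f"{lab}_pct"] = round(100.0 * n_lab / len(cats), percent_decimals) \
                    if cats else 0.0
            out_rows.append(row)

    for variable in CONTINUOUS_VARIABLES:
        pooled_vals = _continuous_values(records, variable)
        if pooled_vals.size == 0:
            warnings.append(f"{variable}: absent from cohort, skipped")
            continue
        row = {"variable": variable, "level": "median (range)", "p_value": np.nan}
        row["pooled_median"] = float(np.median(pooled_vals))
        row["pooled_min"] = float(pooled_vals.min())
        row["pooled_max"] = float(pooled_vals.max())
        per_cohort = {}
        for lab in labels:
            vals = _continuous_values(by_cohort[lab], variable)
            per_cohort[lab] = vals
            if vals.size:
                row[f"{lab}_median"] = float(np.median(vals))
                row[f"{lab}_min"] = float(vals.min())
                row[f"{lab}_max"] = float(vals.max())
        if tested and all(per_cohort[lab].size for lab in ("training", "validation")):
            row["p_value"] = wilcoxon_rank_sum(per_cohort["training"],
                                               per_cohort["validation"]).p_value
        out_rows.append(row)

    return Table1Report(rows=pd.DataFrame(out_rows), tested=tested, warnings=warnings)
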