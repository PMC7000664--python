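"""The iSEND prognostic score (immunotherapy Sex, ECOG, NLR, Delta-NLR).

Score = [male = 1 vs. female = 0]
      + [ECOG >= 2 = 1 vs. ECOG < 2 = 0]
      + [NLR1 >= 5 AND dnlr >= 0 = 2 vs. others = 0]

Risk groups: Good (score 0), Intermediate (score 1), Poor (score >= 2).
The published group table prints the Poor condition with an inverted
inequality sign; the only reading consistent with the score range and the
Good/Intermediate definitions is score >= 2, which is what this module
implements. Both composite boundaries are inclusive: NLR1 exactly 5 with
dnlr exactly 0 scores the 2-point component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cohort import PatientRecord, derive_haematology

GROUPS = ("good", "intermediate", "poor")


@dataclass(frozen=True)
class ISendResult:
    """Integer score 0–4, risk group, and the three addends."""

    score: int
    group: str
    sex_pts: int
    ecog_pts: int
    composite_pts: int


def _group_for(score: int) -> str:
    if score == 0:
        return "good"
    if score == 1:
        return "intermediate"
    return "poor"


def isend_score(sex: str, ecog: int, nlr1: float, dnlr: float) -> ISendResult:
    """Score one patient from sex, ECOG, baseline NLR and delta-NLR.

    Raises ``ValueError`` when any input is missing or invalid; the function
    never returns a partial score.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"score undefined: sex must be 'male' or 'female', got {sex!r}")
    if ecog is None or not 0 <= int(ecog) <= 4:
        raise ValueError(f"score undefined: ecog must be an integer in 0..4, got {ecog!r}")
    if nlr1 is None or not nlr1 > 0:
        raise ValueError(f"score undefined: nlr1 must be a positive real, got {nlr1!r}")
    if dnlr is None:
        raise ValueError("score undefined: dnlr is missing")
    sex_pts = 1 if sex == "male" else 0
    ecog_pts = 1 if int(ecog) >= 2 else 0
    composite_pts = 2 if (nlr1 >= 5.0 and dnlr >= 0.0) else 0
    score = sex_pts + ecog_pts + composite_pts
    return ISendResult(score=score, group=_group_for(score),
                       sex_pts=sex_pts, ecog_pts=ecog_pts, composite_pts=composite_pts)


def score_record(record: PatientRecord) -> ISendResult:
    """Score a validated patient record (NLR1 and NLR2 must be present)."""
    haem = derive_haematology(record)
    return isend_score(record.sex, record.ecog, record.nlr1, haem.dnlr)


@dataclass(frozen=True)
class GroupSummary:
    """Counts and percentages of patients per iSEND risk group."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def assign_groups(
    cohort: Sequence[PatientRecord],
    percent_decimals: int = 1,
) -> tuple[list[ISendResult], GroupSummary]:
    """Score every patient and summarise the Good/Intermediate/Poor split.

    Any patient failing the scoring preconditions aborts the whole call with
    the offending patient id in the error message.
    """
    results: list[ISendResult] = []
    for record in cohort:
        try:
            results.append(score_record(record))
        except ValueError as exc:
            raise ValueError(f"patient {record.patient_id!r}: {exc}") from exc
    counts = {g: 0 for g in GROUPS}
    for res in results:
        counts[res.group] += 1
    total = len(results)
    percentages = {
        g: round(100.0 * counts[g] / total, percent_decimals) if total else 0.0
        for g in GROUPS
    }
    return results, GroupSummary(counts=counts, percentages=percentages, total=total)
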