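"""Clinical cohort data model, CSV I/O, validation and the exclusion cascade.

One row per patient: demographics, ECOG performance status, baseline and
on-treatment neutrophil-to-lymphocyte ratio (NLR1, NLR2), PD-L1 category,
treatment/cohort labels and right-censored OS/PFS outcomes in months.
Event indicators use the dominant survival convention: 1 = event observed,
0 = right-censored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("any", "never", "unknown")
HISTOLOGY_LEVELS = ("squamous", "non_squamous")
EGFR_ALK_LEVELS = ("yes", "no", "unknown")
PDL1_LEVELS = ("p0", "p1_49", "p50plus", "unknown")
TREATMENT_LEVELS = ("pd1_mono", "chemo_only")
LINE_SETTING_LEVELS = ("post_platinum", "first_line", "combination")
COHORT_LEVELS = ("training", "validation", "chemo")

#: canonical column order for cohort CSV files
COLUMNS = (
    "patient_id", "sex", "age", "smoking", "ecog", "histology", "egfr_alk",
    "nlr1", "nlr2", "pdl1", "prior_lines", "treatment", "line_setting",
    "cohort", "os_time", "os_event", "pfs_time", "pfs_event",
)

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


class CohortError(Exception):
    """Fatal I/O or schema problem with a cohort file."""


class HaematologyUndefinedError(ValueError):
    """Raised when dnlr is requested for a record lacking NLR1 or NLR2."""


@dataclass
class PatientRecord:
    """A single patient's covariates and censored outcomes.

    ``nlr1``/``nlr2`` are positive reals or ``None`` when the lab value is
    unavailable; ``pfs_time``/``pfs_event`` may likewise be ``None``.
    Times are months.
    """

    patient_id: str
    sex: str
    age: int
    smoking: str
    ecog: int
    histology: str
    egfr_alk: str
    nlr1: float | None
    nlr2: float | None
    pdl1: str
    prior_lines: int
    treatment: str
    line_setting: str
    cohort: str
    os_time: float
    os_event: int
    pfs_time: float | None = None
    pfs_event: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        checks = (
            (self.sex in SEX_LEVELS, f"sex must be one of {SEX_LEVELS}"),
            (self.age >= 18, "age must be >= 18"),
            (self.smoking in SMOKING_LEVELS, f"smoking must be one of {SMOKING_LEVELS}"),
            (0 <= self.ecog <= 4, "ecog must be an integer in 0..4"),
            (self.histology in HISTOLOGY_LEVELS, f"histology must be one of {HISTOLOGY_LEVELS}"),
            (self.egfr_alk in EGFR_ALK_LEVELS, f"egfr_alk must be one of {EGFR_ALK_LEVELS}"),
            (self.pdl1 in PDL1_LEVELS, f"pdl1 must be one of {PDL1_LEVELS}"),
            (self.prior_lines >= 0, "prior_lines must be >= 0"),
            (self.treatment in TREATMENT_LEVELS, f"treatment must be one of {TREATMENT_LEVELS}"),
            (self.line_setting in LINE_SETTING_LEVELS,
             f"line_setting must be one of {LINE_SETTING_LEVELS}"),
            (self.cohort in COHORT_LEVELS, f"cohort must be one of {COHORT_LEVELS}"),
            (self.os_time >= 0, "os_time must be >= 0"),
            (self.os_event in (0, 1), "os_event must be 0 or 1"),
        )
        for ok, msg in checks:
            if not ok:
                problems.append(msg)
        if self.nlr1 is not None and not self.nlr1 > 0:
            problems.append("nlr1 must be positive")
        if self.nlr2 is not None and not self.nlr2 > 0:
            problems.append("nlr2 must be positive")
        if self.pfs_time is not None:
            if self.pfs_time < 0:
                problems.append("pfs_time must be >= 0")
            if self.pfs_event not in (0, 1):
                problems.append("pfs_event must be 0 or 1 when pfs_time is present")
            if self.pfs_time > self.os_time + 1e-9:
                problems.append("pfs_time must not exceed os_time")
        return problems


@dataclass(frozen=True)
class DerivedHaematology:
    """On-treatment NLR change and the composite biomarker flag.

    ``composite_flag`` is 1 iff NLR1 >= 5 AND dnlr >= 0 — a conjunction
    with both boundaries inclusive.
    """

    dnlr: float
    composite_flag: int


def derive_haematology(record: PatientRecord) -> DerivedHaematology:
    """Compute dnlr = NLR2 − NLR1 and the composite flag for one patient."""
    if record.nlr1 is None or record.nlr2 is None:
        raise HaematologyUndefinedError(
            f"haematology undefined for patient {record.patient_id!r}: "
            "nlr1 and nlr2 must both be present"
        )
    dnlr = record.nlr2 - record.nlr1
    flag = int(record.nlr1 >= 5.0 and dnlr >= 0.0)
    return DerivedHaematology(dnlr=dnlr, composite_flag=flag)


# ---------------------------------------------------------------------------
# CSV reading / writing


def _parse_float(raw: str) -> float | None:
    if raw.strip().lower() in _MISSING_TOKENS:
        return None
    return float(raw)


def _parse_int(raw: str, default: int | None = None) -> int | None:
    if raw.strip().lower() in _MISSING_TOKENS:
        return default
    value = float(raw)
    if value != int(value):
        raise ValueError(f"expected integer, got {raw!r}")
    return int(value)


def _parse_enum(raw: str, levels: Sequence[str], default: str | None = None) -> str | None:
    token = raw.strip().lower()
    if token in _MISSING_TOKENS:
        return default
    if token not in levels:
        raise ValueError(f"{raw!r} not one of {levels}")
    return token


MANDATORY_COLUMNS = ("sex", "ecog", "nlr1", "nlr2", "os_time", "os_event")


def read_cohort(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
) -> tuple[list[PatientRecord], list[str]]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Parameters
    ----------
    path:
        UTF-8, comma-separated file with a header row. Missing values are
        encoded as an empty string or ``NA``.
    schema_config:
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"nlr1": "baseline_nlr"}``.

    Returns
    -------
    (records, diagnostics):
        Accepted records and a list of row-indexed diagnostics for rejected
        rows. Missing optional fields become explicit ``None``/``unknown``
        values, never imputed.

    Raises
    ------
    CohortError
        If the file is unreadable or a mandatory column cannot be mapped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise CohortError(f"cannot read cohort file {path}: {exc}") from exc

    mapping = {col: col for col in COLUMNS}
    if schema_config:
        mapping.update(schema_config)
    missing = [c for c in MANDATORY_COLUMNS if mapping[c] not in frame.columns]
    if missing:
        raise CohortError(
            f"mandatory column(s) not found in {path.name}: "
            + ", ".join(mapping[c] for c in missing)
        )

    def cell(row: pd.Series, canonical: str) -> str:
        name = mapping[canonical]
        return str(row[name]) if name in frame.columns else ""

    records: list[PatientRecord] = []
    diagnostics: list[str] = []
    for idx, row in frame.iterrows():
        try:
            pfs_time = _parse_float(cell(row, "pfs_time"))
            record = PatientRecord(
                patient_id=cell(row, "patient_id").strip() or f"row{idx}",
                sex=_parse_enum(cell(row, "sex"), SEX_LEVELS),
                age=_parse_int(cell(row, "age"), default=18),
                smoking=_parse_enum(cell(row, "smoking"), SMOKING_LEVELS, default="unknown"),
                ecog=_parse_int(cell(row, "ecog")),
                histology=_parse_enum(cell(row, "histology"), HISTOLOGY_LEVELS,
                                      default="non_squamous"),
                egfr_alk=_parse_enum(cell(row, "egfr_alk"), EGFR_ALK_LEVELS, default="unknown"),
                nlr1=_parse_float(cell(row, "nlr1")),
                nlr2=_parse_float(cell(row, "nlr2")),
                pdl1=_parse_enum(cell(row, "pdl1"), PDL1_LEVELS, default="unknown"),
                prior_lines=_parse_int(cell(row, "prior_lines"), default=0),
                treatment=_parse_enum(cell(row, "treatment"), TREATMENT_LEVELS,
                                      default="pd1_mono"),
                line_setting=_parse_enum(cell(row, "line_setting"), LINE_SETTING_LEVELS,
                                         default="post_platinum"),
                cohort=_parse_enum(cell(row, "cohort"), COHORT_LEVELS, default="validation"),
                os_time=_parse_float(cell(row, "os_time")),
                os_event=_parse_int(cell(row, "os_event")),
                pfs_time=pfs_time,
                pfs_event=_parse_int(cell(row, "pfs_event")) if pfs_time is not None else None,
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(f"row {idx}: {exc}")
            continue
        if record.sex is None or record.ecog is None or record.os_time is None \
                or record.os_event is None:
            diagnostics.append(f"row {idx}: mandatory field empty")
            continue
        problems = record.validate()
        if problems:
            diagnostics.extend(f"row {idx}: {p}" for p in problems)
            continue
        records.append(record)
    return records, diagnostics


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as a cohort CSV (full-precision numerics, NA for missing)."""
    frame = records_to_frame(records)
    # pandas' default float formatting is repr-based and round-trips exactly
    frame.to_csv(path, index=False, na_rep="")


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in canonical column order."""
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame` (NaN → None for optional fields)."""
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {col: getattr(row, col) for col in COLUMNS}
        for opt in ("nlr1", "nlr2", "pfs_time", "pfs_event"):
            value = kwargs[opt]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                kwargs[opt] = None
        for integral in ("age", "ecog", "prior_lines", "os_event"):
            kwargs[integral] = int(kwargs[integral])
        if kwargs["pfs_event"] is not None:
            kwargs["pfs_event"] = int(kwargs["pfs_event"])
        records.append(PatientRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# Exclusion cascade

EXCLUSION_REASONS = ("first_line", "combination", "duplicate", "missing_nlr")


def apply_exclusions(
    records: Sequence[PatientRecord],
    exempt_chemo_from_nlr2: bool = False,
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the study's exclusion cascade, in order.

    Removes (1) first-line treatment without previous platinum,
    (2) combination treatment, (3) duplicate patient ids keeping the first
    occurrence in file order, (4) records missing NLR1 or NLR2. The chemo
    control cohort is subject to the same missing-NLR2 rule unless
    ``exempt_chemo_from_nlr2`` is set.

    Returns the analysis set and a tally of exclusion counts per reason.
    The operation is idempotent.
    """
    tally = {reason: 0 for reason in EXCLUSION_REASONS}

    stage1 = []
    for r in records:
        if r.line_setting == "first_line":
            tally["first_line"] += 1
        else:
            stage1.append(r)

    stage2 = []
    for r in stage1:
        if r.line_setting == "combination":
            tally["combination"] += 1
        else:
            stage2.append(r)

    seen: set[str] = set()
    stage3 = []
    for r in stage2:
        if r.patient_id in seen:
            tally["duplicate"] += 1
        else:
            seen.add(r.patient_id)
            stage3.append(r)

    kept = []
    for r in stage3:
        nlr2_ok = r.nlr2 is not None or (exempt_chemo_from_nlr2 and r.cohort == "chemo")
        if r.nlr1 is None or not nlr2_ok:
            tally["missing_nlr"] += 1
        else:
            kept.append(r)

    return kept, tally


def write_exclusion_tally(tally: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(tally), indent=2) + "\n")
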