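"""Cohort CSV input/output and configuration files.

Cohort schema (comma-separated, UTF-8, header required, ``""`` for
missing values, ``#``-prefixed comment lines allowed before the header):

    patient_id, age_years, sex,
    icr_diet_content, icr_diet_frequency, icr_hygiene_habits,
    icr_fluoride_program, icr_family_susceptibility, icr_caries_experience,
    icr_oral_hygiene_status, icr_ph_test,
    cariogram_chance

``icr_<item>`` columns hold integer level indices 0–3. Raw-measurement
columns (``meals_per_day``, ``sugar_exposures_per_day``, ``ph_value``,
``caries_count``, ``restorations_count``, ``missing_teeth_count``,
``mother_status``, ``father_status``) may stand in for the corresponding
``icr_`` column; they are binned on read. Invalid rows are collected
with their row numbers and reported together — never silently dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import CohortValidationError, ValidationError
from .instrument import (
    ITEM_IDS,
    DEFAULT_RULES,
    MeasurementRules,
    PatientRecord,
    map_measurements_to_levels,
)

__all__ = ["read_cohort", "write_cohort", "COHORT_COLUMNS"]

LEVEL_PREFIX = "icr_"

#: Canonical column order for written cohort files.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "sex",
    *(f"{LEVEL_PREFIX}{item}" for item in ITEM_IDS),
    "cariogram_chance",
)

_RAW_COLUMNS = (
    "sugar_exposures_per_day",
    "meals_per_day",
    "mother_status",
    "father_status",
    "caries_count",
    "restorations_count",
    "missing_teeth_count",
    "ph_value",
)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _row_to_record(
    row: pd.Series, columns: Sequence[str], rules: MeasurementRules
) -> PatientRecord:
    pid = row["patient_id"]
    if _is_missing(pid):
        raise ValidationError("missing patient_id")
    raw: dict = {}
    for item in ITEM_IDS:
        col = f"{LEVEL_PREFIX}{item}"
        if col in columns and not _is_missing(row[col]):
            value = row[col]
            level = int(value)
            if level != float(value):
                raise ValidationError(f"column {col!r}: level {value!r} is not an integer")
            raw[item] = level
    for col in _RAW_COLUMNS:
        if col in columns and not _is_missing(row[col]):
            raw[col] = row[col]
    try:
        levels = map_measurements_to_levels(raw, rules)
    except ValidationError as exc:
        raise ValidationError(str(exc)) from exc

    age = None if "age_years" not in columns or _is_missing(row["age_years"]) \
        else float(row["age_years"])
    sex = None if "sex" not in columns or _is_missing(row["sex"]) else str(row["sex"])
    chance = None
    if "cariogram_chance" in columns and not _is_missing(row["cariogram_chance"]):
        chance = float(row["cariogram_chance"])
    return PatientRecord(
        patient_id=str(pid),
        age_years=age,
        sex=sex,
        item_levels=levels,
        cariogram_chance=chance,
    )


def read_cohort(
    path: Union[str, Path],
    rules: MeasurementRules = DEFAULT_RULES,
    on_error: str = "raise",
) -> Union[list[PatientRecord], tuple[list[PatientRecord], list[tuple[int, str]]]]:
    """Read and validate a cohort CSV.

    Row numbers count from 1 at the first data row. With
    ``on_error="raise"`` (default) any invalid row aborts the read with a
    :class:`CohortValidationError` listing every offending row; with
    ``on_error="collect"`` returns ``(records, row_errors)`` instead.
    A malformed header is always a hard error.
    """
    if on_error not in ("raise", "collect"):
        raise ValidationError("on_error must be 'raise' or 'collect'")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype=object, keep_default_na=False)
    columns = list(df.columns)
    if "patient_id" not in columns:
        raise ValidationError(
            f"malformed header: 'patient_id' column missing (got {columns})"
        )
    known = set(COHORT_COLUMNS) | set(_RAW_COLUMNS)
    unknown = [c for c in columns if c not in known]
    if unknown:
        raise ValidationError(f"malformed header: unknown column(s) {unknown}")

    records: list[PatientRecord] = []
    errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            rec = _row_to_record(row, columns, rules)
            if rec.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append((i, str(exc)))
    if on_error == "collect":
        return records, errors
    if errors:
        raise CohortValidationError(errors)
    return records


def write_cohort(
    records: Sequence[PatientRecord],
    path: Union[str, Path],
    header_comment: Optional[str] = None,
) -> None:
    """Write records in the canonical cohort schema.

    ``header_comment`` (e.g. seed and config hash) is written as a
    ``#``-prefixed first line, skipped on read.
    """
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "age_years": "" if rec.age_years is None else rec.age_years,
            "sex": "" if rec.sex is None else rec.sex,
            "cariogram_chance": "" if rec.cariogram_chance is None else rec.cariogram_chance,
        }
        for item in ITEM_IDS:
            col = f"{LEVEL_PREFIX}{item}"
            row[col] = rec.item_levels.get(item, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
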