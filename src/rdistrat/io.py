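"""Read and write cohorts as delimited text.

A cohort lives in a directory holding two RFC-4180 CSV files mirroring the
case-report-form structure:

``cycles.csv``
    One row per administered cycle: patient_id, cycle_index, admin_day,
    dox_dose, cddp_dose, delayed, reduced, adaptation_cause.
``patients.csv``
    One row per patient: patient_id, arm, surgery_day, end_of_therapy_day,
    event_day, event_observed, censor_day.

Booleans are serialized as 0/1, enums as lowercase tokens, absent values as
empty fields (never sentinel numbers). An optional ``meta.json`` carries
free-text provenance. ``read_cohort(write_cohort(c))`` reproduces ``c``
field-for-field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .cohort import (
    AdaptationCause,
    Arm,
    Cohort,
    CycleRecord,
    SchemaError,
    TreatmentCourse,
    ValidationError,
)

CYCLES_FILE = "cycles.csv"
PATIENTS_FILE = "patients.csv"
META_FILE = "meta.json"

CYCLE_COLUMNS = [
    "patient_id",
    "cycle_index",
    "admin_day",
    "dox_dose",
    "cddp_dose",
    "delayed",
    "reduced",
    "adaptation_cause",
]
PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "surgery_day",
    "end_of_therapy_day",
    "event_day",
    "event_observed",
    "censor_day",
]


def _parse_int(value: str, column: str, context: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise SchemaError(f"{context}: column {column!r} has non-integer value {value!r}")


def _parse_opt_int(value: str, column: str, context: str) -> int | None:
    if value == "":
        return None
    return _parse_int(value, column, context)


def _parse_float(value: str, column: str, context: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"{context}: column {column!r} has non-numeric value {value!r}")


def _parse_bool(value: str, column: str, context: str) -> bool:
    if value == "0":
        return False
    if value == "1":
        return True
    raise SchemaError(f"{context}: column {column!r} must be 0/1, got {value!r}")


def _parse_enum(enum_cls, value: str, column: str, context: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise SchemaError(f"{context}: column {column!r} has unknown token {value!r}")


def _check_header(header: list[str] | None, required: list[str], fname: str) -> None:
    if header is None:
        raise SchemaError(f"{fname}: empty file, expected a header row")
    for col in required:
        if col not in header:
            raise SchemaError(f"{fname}: missing required column {col!r}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize a validated cohort into the two-file CSV layout at *path*."""
    cohort.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / CYCLES_FILE, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CYCLE_COLUMNS)
        for course in cohort:
            for cyc in course.cycles:
                writer.writerow(
                    [
                        course.patient_id,
                        cyc.cycle_index,
                        cyc.admin_day,
                        repr(float(cyc.dox_dose)),
                        repr(float(cyc.cddp_dose)),
                        int(cyc.delayed),
                        int(cyc.reduced),
                        cyc.adaptation_cause.value,
                    ]
                )

    with open(path / PATIENTS_FILE, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_COLUMNS)
        for course in cohort:
            writer.writerow(
                [
                    course.patient_id,
                    course.arm.value,
                    "" if course.surgery_day is None else course.surgery_day,
                    course.end_of_therapy_day,
                    "" if course.event_day is None else course.event_day,
                    int(course.event_observed),
                    course.censor_day,
                ]
            )

    with open(path / META_FILE, "w", encoding="utf-8") as fh:
        json.dump({"provenance": cohort.provenance}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort from the two-file CSV layout at *path*.

    Raises
    ------
    SchemaError
        Missing file or column, or an unparseable field.
    ValidationError
        Duplicate (patient_id, cycle_index), cycles for an unknown patient,
        non-monotone admin days, or any other data-model violation.
    """
    path = Path(path)
    cycles_path = path / CYCLES_FILE
    patients_path = path / PATIENTS_FILE
    for p in (cycles_path, patients_path):
        if not p.is_file():
            raise SchemaError(f"missing cohort file {p}")

    courses: list[TreatmentCourse] = []
    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, PATIENT_COLUMNS, PATIENTS_FILE)
        idx = {col: header.index(col) for col in PATIENT_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            ctx = f"{PATIENTS_FILE}:{lineno}"
            courses.append(
                TreatmentCourse(
                    patient_id=row[idx["patient_id"]],
                    arm=_parse_enum(Arm, row[idx["arm"]], "arm", ctx),
                    surgery_day=_parse_opt_int(row[idx["surgery_day"]], "surgery_day", ctx),
                    end_of_therapy_day=_parse_int(
                        row[idx["end_of_therapy_day"]], "end_of_therapy_day", ctx
                    ),
                    event_day=_parse_opt_int(row[idx["event_day"]], "event_day", ctx),
                    event_observed=_parse_bool(
                        row[idx["event_observed"]], "event_observed", ctx
                    ),
                    censor_day=_parse_int(row[idx["censor_day"]], "censor_day", ctx),
                )
            )

    by_id = {c.patient_id: c for c in courses}
    if len(by_id) != len(courses):
        raise ValidationError(f"{PATIENTS_FILE}: duplicate patient_id")

    seen_cycles: set[tuple[str, int]] = set()
    with open(cycles_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, CYCLE_COLUMNS, CYCLES_FILE)
        idx = {col: header.index(col) for col in CYCLE_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            ctx = f"{CYCLES_FILE}:{lineno}"
            pid = row[idx["patient_id"]]
            if pid not in by_id:
                raise ValidationError(f"{ctx}: cycle for unknown patient {pid!r}")
            cycle_index = _parse_int(row[idx["cycle_index"]], "cycle_index", ctx)
            if (pid, cycle_index) in seen_cycles:
                raise ValidationError(
                    f"{ctx}: duplicate cycle {cycle_index} for patient {pid!r}"
                )
            seen_cycles.add((pid, cycle_index))
            by_id[pid].cycles.append(
                CycleRecord(
                    cycle_index=cycle_index,
                    admin_day=_parse_int(row[idx["admin_day"]], "admin_day", ctx),
                    dox_dose=_parse_float(row[idx["dox_dose"]], "dox_dose", ctx),
                    cddp_dose=_parse_float(row[idx["cddp_dose"]], "cddp_dose", ctx),
                    delayed=_parse_bool(row[idx["delayed"]], "delayed", ctx),
                    reduced=_parse_bool(row[idx["reduced"]], "reduced", ctx),
                    adaptation_cause=_parse_enum(
                        AdaptationCause, row[idx["adaptation_cause"]], "adaptation_cause", ctx
                    ),
                )
            )

    for course in courses:
        course.cycles.sort(key=lambda c: c.cycle_index)

    provenance: dict[str, str] = {}
    meta_path = path / META_FILE
    if meta_path.is_file():
        with open(meta_path, encoding="utf-8") as fh:
            provenance = json.load(fh).get("provenance", {})

    cohort = Cohort(courses=courses, provenance=provenance)
    cohort.validate()
    return cohort
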