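"""Reading, normalizing and filtering inpatient admission records.

The analysis unit is one baseline hospitalization per inpatient, with the
diagnosis list reduced to the set of distinct 3-character ICD-10 categories
from Chapters 1–14.  This module implements that reduction:

* :func:`read_records` parses a delimited cohort table,
* :func:`normalize_records` truncates codes to categories,
* :func:`filter_scope` drops out-of-scope codes and rejects records whose
  codes all fall in Chapters 15–22,
* :func:`select_baseline` keeps each patient's earliest admission,
* :func:`stratify` partitions the cohort by sex and/or 5-year age band.

Filtering outcomes are tallied in a :class:`FilterReport` so data loss is
auditable.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .icd10 import IN_SCOPE_CHAPTERS, CodeError, normalize_code

__all__ = [
    "AdmissionRecord",
    "CohortStratum",
    "Dialect",
    "FilterReport",
    "IngestError",
    "AGE_BANDS",
    "read_records",
    "write_records",
    "normalize_records",
    "filter_scope",
    "select_baseline",
    "stratify",
    "age_band_of",
    "prepare_strata",
]

#: 5-year age bands of the middle-aged study population, inclusive bounds.
AGE_BANDS: tuple[tuple[int, int], ...] = ((40, 44), (45, 49), (50, 54), (55, 59))

REQUIRED_COLUMNS = ("record_id", "patient_id", "sex", "age", "admission_date", "codes")


class IngestError(ValueError):
    """Fatal configuration or integrity error while reading a cohort table."""


@dataclass(frozen=True, slots=True)
class Dialect:
    """Delimiters of the cohort table: field separator and code-list separator."""

    delimiter: str = ","
    code_sep: str = ";"


@dataclass(frozen=True, slots=True)
class AdmissionRecord:
    """One hospitalization: patient, sex, age at admission, date, diagnosis codes.

    ``codes`` holds raw strings straight after parsing and 3-character
    categories after :func:`normalize_records`; multiple raw codes collapsing
    to the same category count once (the set is the analysis object).
    """

    record_id: str
    patient_id: str
    sex: Literal["male", "female"]
    age_years: int
    admission_date: _dt.date
    codes: frozenset[str]


@dataclass
class FilterReport:
    """Tally of rows/records removed at each ingest stage."""

    rows_read: int = 0
    row_errors: list[str] = field(default_factory=list)
    bad_codes: Counter = field(default_factory=Counter)
    rejected_out_of_scope: int = 0
    dropped_codes: int = 0
    non_baseline_removed: int = 0
    age_out_of_range: int = 0

    def to_json(self) -> str:
        payload = {
            "rows_read": self.rows_read,
            "row_errors": self.row_errors,
            "bad_codes": dict(self.bad_codes),
            "rejected_out_of_scope": self.rejected_out_of_scope,
            "dropped_codes": self.dropped_codes,
            "non_baseline_removed": self.non_baseline_removed,
            "age_out_of_range": self.age_out_of_range,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass(frozen=True)
class CohortStratum:
    """An analysis cohort: baseline in-scope records of one sex/age cell."""

    label: str
    sex: Literal["male", "female", "all"]
    age_band: tuple[int, int]
    records: tuple[AdmissionRecord, ...]

    @property
    def n_records(self) -> int:
        return len(self.records)

    def observed_codes(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.codes
        return out


def _parse_sex(value: str) -> Literal["male", "female"]:
    v = value.strip().lower()
    if v in ("male", "m"):
        return "male"
    if v in ("female", "f"):
        return "female"
    raise ValueError(f"unrecognized sex {value!r}")


def read_records(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[AdmissionRecord], FilterReport]:
    """Parse a delimited cohort table into admission records.

    The header must name ``record_id, patient_id, sex, age, admission_date,
    codes``; the codes column holds a ``code_sep``-separated list.  Rows with
    unparseable age/date/sex or an empty code list are collected in the
    report (with row numbers) rather than aborting the parse; a missing
    column or a duplicate ``record_id`` is fatal.
    """
    dialect = dialect or Dialect()
    report = FilterReport()
    records: list[AdmissionRecord] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        missing = [c for c in REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise IngestError(f"missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            report.rows_read += 1
            try:
                rid = row["record_id"].strip()
                if rid in seen_ids:
                    raise IngestError(f"duplicate record_id {rid!r} at row {lineno}")
                codes = frozenset(
                    c.strip() for c in row["codes"].split(dialect.code_sep) if c.strip()
                )
                if not codes:
                    raise ValueError("empty codes field")
                rec = AdmissionRecord(
                    record_id=rid,
                    patient_id=row["patient_id"].strip(),
                    sex=_parse_sex(row["sex"]),
                    age_years=int(row["age"]),
                    admission_date=_dt.date.fromisoformat(row["admission_date"].strip()),
                    codes=codes,
                )
                if rec.age_years < 0:
                    raise ValueError("negative age")
            except IngestError:
                raise
            except Exception as exc:  # row-level: collect and continue
                report.row_errors.append(f"row {lineno}: {exc}")
                continue
            seen_ids.add(rid)
            records.append(rec)
    return records, report


def write_records(
    records: Iterable[AdmissionRecord], path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write records back in the canonical cohort-table format."""
    dialect = dialect or Dialect()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.patient_id,
                    r.sex,
                    r.age_years,
                    r.admission_date.isoformat(),
                    dialect.code_sep.join(sorted(r.codes)),
                ]
            )


def normalize_records(
    records: Iterable[AdmissionRecord], report: FilterReport | None = None
) -> list[AdmissionRecord]:
    """Truncate every code to its 3-character category.

    Unparseable codes are dropped and tallied; a record keeps its parseable
    codes.  A record whose codes are all unparseable is reported as a row
    error.
    """
    report = report if report is not None else FilterReport()
    out: list[AdmissionRecord] = []
    for rec in records:
        kept: set[str] = set()
        for raw in rec.codes:
            try:
                kept.add(normalize_code(raw).code3)
            except CodeError:
                report.bad_codes[raw] += 1
        if not kept:
            report.row_errors.append(f"record {rec.record_id}: no parseable codes")
            continue
        out.append(replace(rec, codes=frozenset(kept)))
    return out


def filter_scope(
    record: AdmissionRecord, report: FilterReport | None = None
) -> AdmissionRecord | None:
    """Drop codes outside Chapters 1–14; reject the record if none remain.

    Records carrying only Chapter 15–22 codes (obstetric, perinatal,
    congenital, symptom, injury, external-cause, contact and special-purpose
    categories) are excluded from the analysis; in-scope codes of mixed
    records are retained.  Idempotent.
    """
    from .icd10 import chapter_of

    kept = frozenset(c for c in record.codes if chapter_of(c) in IN_SCOPE_CHAPTERS)
    if not kept:
        if report is not None:
            report.rejected_out_of_scope += 1
        return None
    if report is not None:
        report.dropped_codes += len(record.codes) - len(kept)
    if kept == record.codes:
        return record
    return replace(record, codes=kept)


def select_baseline(
    records: Sequence[AdmissionRecord], report: FilterReport | None = None
) -> list[AdmissionRecord]:
    """Keep each patient's first admission (earliest date).

    Date ties break on the lexicographically smallest ``record_id`` so the
    selection is deterministic.  Output order follows first appearance of
    each patient in the input.
    """
    best: dict[str, AdmissionRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.patient_id)
        if cur is None:
            best[rec.patient_id] = rec
            order.append(rec.patient_id)
        elif (rec.admission_date, rec.record_id) < (cur.admission_date, cur.record_id):
            best[rec.patient_id] = rec
    if report is not None:
        report.non_baseline_removed += len(records) - len(best)
    return [best[p] for p in order]


def age_band_of(age: int) -> tuple[int, int]:
    """The 5-year band containing ``age``; bands are inclusive on both ends."""
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return (lo, hi)
    raise ValueError(f"age {age} outside the study range 40-59")


def stratify(
    records: Sequence[AdmissionRecord],
    scheme: Literal["all", "sex", "sex_age"] = "sex_age",
    label_prefix: str = "",
) -> dict[str, CohortStratum]:
    """Partition a filtered cohort into disjoint, exhaustive strata.

    ``all`` yields a single stratum, ``sex`` one per sex, ``sex_age`` the
    eight sex × 5-year-band cells.  All records must already lie within
    ages 40–59.
    """
    groups: dict[tuple, list[AdmissionRecord]] = {}
    for rec in records:
        if scheme == "all":
            key: tuple = ("all", (40, 59))
        elif scheme == "sex":
            key = (rec.sex, (40, 59))
        elif scheme == "sex_age":
            key = (rec.sex, age_band_of(rec.age_years))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        groups.setdefault(key, []).append(rec)
    out: dict[str, CohortStratum] = {}
    for (sex, band), recs in sorted(groups.items()):
        label = f"{label_prefix}{sex}_{band[0]}-{band[1]}"
        out[label] = CohortStratum(
            label=label, sex=sex, age_band=band, records=tuple(recs)
        )
    return out


def prepare_strata(
    records: Sequence[AdmissionRecord],
    scheme: Literal["all", "sex", "sex_age"] = "sex_age",
    report: FilterReport | None = None,
    label_prefix: str = "",
) -> dict[str, CohortStratum]:
    """Full record-level pipeline: normalize, scope-filter, baseline, age, stratify."""
    report = report if report is not None else FilterReport()
    normed = normalize_records(records, report)
    scoped = [r for r in (filter_scope(rec, report) for rec in normed) if r is not None]
    baseline = select_baseline(scoped, report)
    aged = [r for r in baseline if 40 <= r.age_years <= 59]
    report.age_out_of_range += len(baseline) - len(aged)
    return stratify(aged, scheme, label_prefix=label_prefix)
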