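"""Validating CSV readers and writers for the four inputs and the results.

Files are UTF-8, comma-separated, RFC-4180 quoted, with exact header rows.
Dates are ISO-8601.  Enumerated tokens are accepted case-insensitively and
normalised to lower case (sex stays upper case: F/M).  Malformed rows are
rejected individually and reported in a :class:`ValidationReport` rather
than aborting the whole read; a wrong header or an unreadable file aborts.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from .model import (
    ACTS,
    ENROLMENT_KINDS,
    MORBIDITY_BANDS,
    PAYMENT_MODES,
    PRACTICE_SETTINGS,
    SEXES,
    VISIT_SETTINGS,
    AttachmentResult,
    EnrolmentSpell,
    PatientProfile,
    PhysicianProfile,
    VisitRecord,
)

log = logging.getLogger(__name__)

PATIENT_HEADER = [
    "patient_id", "birth_date", "sex", "resident_flag", "ltc_flag",
    "death_date", "diabetes_flag", "morbidity_band",
]
PHYSICIAN_HEADER = ["physician_id", "payment_mode", "practice_setting"]
VISIT_HEADER = ["patient_id", "physician_id", "service_date", "setting", "act"]
ENROLMENT_HEADER = ["patient_id", "physician_id", "kind", "start_date", "end_date"]
RESULT_HEADER = [
    "patient_id", "attachment_type", "subtype", "attached_physician_id",
    "upc_score", "dimension_flags",
]


class SchemaError(ValueError):
    """The file-level structure (header, vocabulary) does not match the schema."""


@dataclass
class ValidationReport:
    """Row-level outcome of a read: what was read, what was rejected and why."""

    n_rows_read: int = 0
    n_rows_rejected: int = 0
    messages: List[Tuple[int, str]] = field(default_factory=list)

    def reject(self, row_number: int, rule: str) -> None:
        self.n_rows_rejected += 1
        self.messages.append((row_number, rule))
        log.debug("row %d rejected: %s", row_number, rule)


def _parse_date(token: str) -> dt.date:
    return dt.date.fromisoformat(token.strip())


def _parse_opt_date(token: str) -> Optional[dt.date]:
    token = token.strip()
    return None if token == "" else dt.date.fromisoformat(token)


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in {"1", "true", "t", "yes"}:
        return True
    if t in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"not a boolean token: {token!r}")


def _norm(token: str, vocab: frozenset, what: str) -> str:
    t = token.strip().lower()
    if t not in vocab:
        raise SchemaError(f"unknown {what} token {token!r}")
    return t


def _open_rows(path, expected_header: List[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {expected_header}")
        if header != expected_header:
            raise SchemaError(
                f"{path}: header {header} does not match schema {expected_header}"
            )
        yield from reader


def read_patients(path) -> Tuple[List[PatientProfile], ValidationReport]:
    report = ValidationReport()
    out: List[PatientProfile] = []
    seen = set()
    for i, row in enumerate(_open_rows(path, PATIENT_HEADER), start=2):
        report.n_rows_read += 1
        try:
            pid = row[0].strip()
            if pid in seen:
                raise ValueError("duplicate patient_id")
            profile = PatientProfile(
                patient_id=pid,
                birth_date=_parse_date(row[1]),
                sex=row[2].strip().upper(),
                resident_flag=_parse_bool(row[3]),
                long_term_care_flag=_parse_bool(row[4]),
                death_date=_parse_opt_date(row[5]),
                diabetes_flag=_parse_bool(row[6]),
                morbidity_band=row[7].strip().lower(),
            )
        except (ValueError, IndexError) as exc:
            report.reject(i, str(exc))
            continue
        seen.add(profile.patient_id)
        out.append(profile)
    return out, report


def read_physicians(path) -> Tuple[List[PhysicianProfile], ValidationReport]:
    report = ValidationReport()
    out: List[PhysicianProfile] = []
    seen = set()
    for i, row in enumerate(_open_rows(path, PHYSICIAN_HEADER), start=2):
        report.n_rows_read += 1
        try:
            pid = row[0].strip()
            if pid in seen:
                raise ValueError("duplicate physician_id")
            profile = PhysicianProfile(
                physician_id=pid,
                payment_mode=_norm(row[1], PAYMENT_MODES, "payment mode"),
                practice_setting=_norm(row[2], PRACTICE_SETTINGS, "practice setting"),
            )
        except (ValueError, IndexError) as exc:
            report.reject(i, str(exc))
            continue
        seen.add(profile.physician_id)
        out.append(profile)
    return out, report


def read_visits(path, *, on_cme_duplicate: str = "drop"
                ) -> Tuple[List[VisitRecord], ValidationReport]:
    """Read visit claims, enforcing the once-a-year billing rule for CMEs.

    A physician cannot bill a complete medical examination (CME) more than
    once per patient per calendar year in a primary-care clinic.  Surplus
    CME rows for the same (patient, physician, year) are dropped, keeping
    the earliest ("drop", default), or abort the read ("error").
    """
    if on_cme_duplicate not in {"drop", "error"}:
        raise ValueError("on_cme_duplicate must be 'drop' or 'error'")
    report = ValidationReport()
    parsed: List[Tuple[int, VisitRecord]] = []
    for i, row in enumerate(_open_rows(path, VISIT_HEADER), start=2):
        report.n_rows_read += 1
        try:
            rec = VisitRecord(
                patient_id=row[0].strip(),
                physician_id=row[1].strip(),
                service_date=_parse_date(row[2]),
                setting=_norm(row[3], VISIT_SETTINGS, "setting"),
                act=_norm(row[4], ACTS, "act"),
            )
        except (ValueError, IndexError) as exc:
            report.reject(i, str(exc))
            continue
        parsed.append((i, rec))

    # once-a-year CME rule: keep the earliest CME per (patient, physician, year)
    best: dict = {}
    for i, rec in parsed:
        if rec.act != "cme":
            continue
        key = (rec.patient_id, rec.physician_id, rec.service_date.year)
        if key not in best or rec.service_date < best[key][1].service_date:
            best[key] = (i, rec)
    kept_cme_rows = {i for i, _ in best.values()}
    out: List[VisitRecord] = []
    for i, rec in parsed:
        if rec.act == "cme" and i not in kept_cme_rows:
            if on_cme_duplicate == "error":
                raise SchemaError(
                    f"row {i}: duplicate CME billing for "
                    f"({rec.patient_id}, {rec.physician_id}, {rec.service_date.year})"
                )
            report.reject(i, "cme_once_per_year")
            continue
        out.append(rec)
    return out, report


def read_enrolment(path) -> Tuple[List[EnrolmentSpell], ValidationReport]:
    report = ValidationReport()
    out: List[EnrolmentSpell] = []
    for i, row in enumerate(_open_rows(path, ENROLMENT_HEADER), start=2):
        report.n_rows_read += 1
        try:
            rec = EnrolmentSpell(
                patient_id=row[0].strip(),
                physician_id=row[1].strip(),
                kind=_norm(row[2], ENROLMENT_KINDS, "enrolment kind"),
                start_date=_parse_date(row[3]),
                end_date=_parse_opt_date(row[4]),
            )
        except (ValueError, IndexError) as exc:
            report.reject(i, str(exc))
            continue
        out.append(rec)
    return out, report


# ---------------------------------------------------------------------------
# writers (inverse of the readers; write∘read is the identity on valid lists)

def _fmt_date(day: Optional[dt.date]) -> str:
    return "" if day is None else day.isoformat()


def _fmt_bool(flag: bool) -> str:
    return "1" if flag else "0"


def _write(path, header: List[str], rows: Iterable[List[str]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def write_patients(path, patients: Iterable[PatientProfile]) -> None:
    _write(path, PATIENT_HEADER, (
        [p.patient_id, p.birth_date.isoformat(), p.sex,
         _fmt_bool(p.resident_flag), _fmt_bool(p.long_term_care_flag),
         _fmt_date(p.death_date), _fmt_bool(p.diabetes_flag), p.morbidity_band]
        for p in patients
    ))


def write_physicians(path, physicians: Iterable[PhysicianProfile]) -> None:
    _write(path, PHYSICIAN_HEADER, (
        [d.physician_id, d.payment_mode, d.practice_setting] for d in physicians
    ))


def write_visits(path, visits: Iterable[VisitRecord]) -> None:
    _write(path, VISIT_HEADER, (
        [v.patient_id, v.physician_id, v.service_date.isoformat(), v.setting, v.act]
        for v in visits
    ))


def write_enrolment(path, spells: Iterable[EnrolmentSpell]) -> None:
    _write(path, ENROLMENT_HEADER, (
        [s.patient_id, s.physician_id, s.kind, s.start_date.isoformat(),
         _fmt_date(s.end_date)]
        for s in spells
    ))


def write_results(path, results: Iterable[AttachmentResult]) -> None:
    """One row per patient; UPC as an exact fraction string, empty if undefined."""
    _write(path, RESULT_HEADER, (
        [r.patient_id, str(r.attachment_type), r.subtype or "",
         r.attached_physician_id or "",
         "" if r.upc_score is None else f"{r.upc_score.numerator}/{r.upc_score.denominator}",
         ";".join(sorted(r.dimension_flags))]
        for r in results
    ))


def read_results(path) -> Tuple[List[AttachmentResult], ValidationReport]:
    from fractions import Fraction

    report = ValidationReport()
    out: List[AttachmentResult] = []
    for i, row in enumerate(_open_rows(path, RESULT_HEADER), start=2):
        report.n_rows_read += 1
        try:
            upc = None
            if row[4].strip():
                num, den = row[4].split("/")
                upc = Fraction(int(num), int(den))
            flags = frozenset(t for t in row[5].split(";") if t)
            rec = AttachmentResult(
                patient_id=row[0].strip(),
                attachment_type=int(row[1]),
                subtype=row[2].strip() or None,
                attached_physician_id=row[3].strip() or None,
                dimension_flags=flags,
                upc_score=upc,
            )
        except (ValueError, IndexError) as exc:
            report.reject(i, str(exc))
            continue
        out.append(rec)
    return out, report
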