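"""Core record types and interval arithmetic for attachment classification.

All rules in the pipeline are evaluated against a two-year observation
window.  Dates are ``datetime.date`` objects (ISO-8601 in files, no
time-of-day).  Intervals — enrolment spells and the study window itself —
are closed on both ends, so a window 2008-04-01..2010-03-31 is 730 days
long.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

SEXES = frozenset({"F", "M"})
PAYMENT_MODES = frozenset({"fee_for_service", "time_basis"})
PRACTICE_SETTINGS = frozenset({"phc_clinic", "community_health_centre", "teaching_unit"})
VISIT_SETTINGS = frozenset({"phc_clinic", "emergency_room", "hospital_inpatient"})
ACTS = frozenset({"visit", "cme"})
ENROLMENT_KINDS = frozenset({"fmg", "vulnerable"})
MORBIDITY_BANDS = frozenset({"low", "moderate", "high"})

#: dimension-flag tokens attached to every classification result
DIMENSION_FLAGS = (
    "fmg_enrolled",
    "vulnerable_enrolled",
    "two_cme",
    "one_cme",
    "upc_ge_75",
    "single_visit",
)

SUBTYPES = ("8a", "8b", "8c", "8d", "8e")


class InvalidInputError(ValueError):
    """An operation received arguments outside its domain."""


@dataclass(frozen=True)
class StudyWindow:
    """Closed two-year observation interval.

    Parameters
    ----------
    start_date, end_date
        First and last day of the window (both included).
    min_enrolment_days
        Day count operationalising the "18 months of enrolment" rule.
        Default 548 = ceil(1.5 * 365.25).
    """

    start_date: dt.date
    end_date: dt.date
    min_enrolment_days: int = 548

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise InvalidInputError("window end_date must be after start_date")
        n = self.length_days
        if n < 700 or n > 760:
            warnings.warn(
                f"study window is {n} days long; the classification rules are "
                "calibrated for a ~two-year (730-day) window",
                stacklevel=2,
            )
        if self.min_enrolment_days > n:
            raise InvalidInputError(
                "min_enrolment_days exceeds the window length"
            )

    @property
    def length_days(self) -> int:
        """Number of days in the closed interval."""
        return (self.end_date - self.start_date).days + 1

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date


#: window used throughout the examples: Quebec fiscal years 2008-09 / 2009-10
DEFAULT_WINDOW = StudyWindow(dt.date(2008, 4, 1), dt.date(2010, 3, 31))


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    birth_date: dt.date
    sex: str
    resident_flag: bool
    long_term_care_flag: bool
    death_date: Optional[dt.date]
    diabetes_flag: bool
    morbidity_band: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidInputError(f"unknown sex token {self.sex!r}")
        if self.morbidity_band not in MORBIDITY_BANDS:
            raise InvalidInputError(f"unknown morbidity band {self.morbidity_band!r}")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise InvalidInputError("death_date precedes birth_date")


@dataclass(frozen=True)
class PhysicianProfile:
    physician_id: str
    payment_mode: str
    practice_setting: str

    def __post_init__(self) -> None:
        if self.payment_mode not in PAYMENT_MODES:
            raise InvalidInputError(f"unknown payment mode {self.payment_mode!r}")
        if self.practice_setting not in PRACTICE_SETTINGS:
            raise InvalidInputError(f"unknown practice setting {self.practice_setting!r}")


@dataclass(frozen=True)
class VisitRecord:
    """One billed ambulatory contact (fee-for-service claim row)."""

    patient_id: str
    physician_id: str
    service_date: dt.date
    setting: str
    act: str

    def __post_init__(self) -> None:
        if self.setting not in VISIT_SETTINGS:
            raise InvalidInputError(f"unknown visit setting {self.setting!r}")
        if self.act not in ACTS:
            raise InvalidInputError(f"unknown act token {self.act!r}")


@dataclass(frozen=True)
class EnrolmentSpell:
    """One registry interval binding a patient to a physician.

    ``end_date`` may be ``None`` for an open spell; interval arithmetic
    censors such spells at the window end (the registry is an annual
    snapshot, so open spells are common).
    """

    patient_id: str
    physician_id: str
    kind: str
    start_date: dt.date
    end_date: Optional[dt.date]

    def __post_init__(self) -> None:
        if self.kind not in ENROLMENT_KINDS:
            raise InvalidInputError(f"unknown enrolment kind {self.kind!r}")
        if self.end_date is not None and self.end_date < self.start_date:
            raise InvalidInputError("spell end_date precedes start_date")


@dataclass(frozen=True)
class AttachmentResult:
    """The classifier's verdict for one patient.

    ``attachment_type`` 1-7 means attached (with the attached physician
    identified); 8 means non-attached, optionally refined into subtypes
    8a-8e.  ``dimension_flags`` records which of the three underlying
    dimensions (enrolment, complete medical examination, concentration of
    visits) the patient holds, independently of which rule fired.
    """

    patient_id: str
    attachment_type: int
    subtype: Optional[str]
    attached_physician_id: Optional[str]
    dimension_flags: frozenset = field(default_factory=frozenset)
    upc_score: Optional[Fraction] = None

    def __post_init__(self) -> None:
        if self.attachment_type not in range(1, 9):
            raise InvalidInputError(f"attachment_type must be 1..8, got {self.attachment_type}")
        if self.attachment_type <= 7 and self.attached_physician_id is None:
            raise InvalidInputError("types 1-7 require an attached physician")
        if self.attachment_type == 8 and self.attached_physician_id is not None:
            raise InvalidInputError("type 8 must not name an attached physician")
        if self.subtype is not None:
            if self.attachment_type != 8:
                raise InvalidInputError("subtype only applies to type 8")
            if self.subtype not in SUBTYPES:
                raise InvalidInputError(f"unknown subtype {self.subtype!r}")
        unknown = set(self.dimension_flags) - set(DIMENSION_FLAGS)
        if unknown:
            raise InvalidInputError(f"unknown dimension flags {sorted(unknown)}")


def age_at(profile: PatientProfile, reference: dt.date) -> int:
    """Completed years between birth and the reference date."""
    birth = profile.birth_date
    if reference < birth:
        raise InvalidInputError("reference date precedes birth date")
    return (
        reference.year
        - birth.year
        - ((reference.month, reference.day) < (birth.month, birth.day))
    )


def overlap_days(spell: EnrolmentSpell, window: StudyWindow) -> int:
    """Days in the intersection of a spell with the window (closed intervals).

    An open spell is censored at the window end.  Disjoint intervals give 0.
    """
    end = spell.end_date if spell.end_date is not None else window.end_date
    lo = max(spell.start_date, window.start_date)
    hi = min(end, window.end_date)
    if hi < lo:
        return 0
    return (hi - lo).days + 1
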