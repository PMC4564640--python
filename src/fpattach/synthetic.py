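"""Synthetic claims generator with planted ground-truth attachment types.

Two entry points:

* :func:`make_fixture` builds one minimal, fully deterministic patient per
  attachment type (1-8 and non-attached subtypes 8a-8e), with boundary
  variants sitting exactly on the rule thresholds (548 enrolment days, UPC
  exactly 3/4, CMEs in consecutive calendar years).
* :func:`simulate` draws a whole population from a type mixture and
  realises each patient through the type's generative recipe, so the
  planted type is satisfied *by construction* (no rejection sampling) and
  recorded in a truth table.

The default type mixture reproduces the distribution observed in the
two-year Montreal claims study the rules are calibrated against (about 7%
enrolled in family medicine groups, 16% enrolled as vulnerable, ... 32%
non-attached), so default simulations resemble that population.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import claims_io
from .model import (
    DEFAULT_WINDOW,
    EnrolmentSpell,
    InvalidInputError,
    PatientProfile,
    PhysicianProfile,
    StudyWindow,
    VisitRecord,
)

# observed study-population shares for types 1..8 (percent/100, re-normalised)
_RAW_MIXTURE = (0.072, 0.162, 0.053, 0.081, 0.080, 0.127, 0.105, 0.319)
DEFAULT_TYPE_MIXTURE: Tuple[float, ...] = tuple(
    x / sum(_RAW_MIXTURE) for x in _RAW_MIXTURE
)

# conditional split of the non-attached share into subtypes 8a..8e
_RAW_SUBTYPE = (0.004, 0.010, 0.046, 0.144, 0.115)
DEFAULT_SUBTYPE_SPLIT: Tuple[float, ...] = tuple(
    x / sum(_RAW_SUBTYPE) for x in _RAW_SUBTYPE
)

_AGE_BANDS = ((20, 44), (45, 59), (60, 74), (75, 94))
_BASE_AGE_WEIGHTS = (0.438, 0.275, 0.181, 0.106)
_BASE_MORBIDITY = (0.425, 0.473, 0.102)

FIXTURE_TYPES = ("1", "2", "3", "4", "5", "6", "7", "8", "8a", "8b", "8c", "8d", "8e")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 20_000
    type_mixture: Tuple[float, ...] = DEFAULT_TYPE_MIXTURE
    subtype_split: Tuple[float, ...] = DEFAULT_SUBTYPE_SPLIT
    mean_visits: float = 4.0
    n_physicians: int = 200
    fmg_fraction: float = 0.35
    time_basis_fraction: float = 0.15
    window: StudyWindow = DEFAULT_WINDOW
    covariate_gradients: bool = False

    def __post_init__(self) -> None:
        if len(self.type_mixture) != 8:
            raise InvalidInputError("type_mixture must have 8 entries (types 1-8)")
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise InvalidInputError("type_mixture must sum to 1")
        if len(self.subtype_split) != 5:
            raise InvalidInputError("subtype_split must have 5 entries (8a-8e)")
        if abs(sum(self.subtype_split) - 1.0) > 1e-9:
            raise InvalidInputError("subtype_split must sum to 1")
        if min(self.n_patients, self.n_physicians) <= 0:
            raise InvalidInputError("counts must be positive")
        if self.mean_visits <= 0:
            raise InvalidInputError("mean_visits must be positive")


@dataclass
class TruthRow:
    patient_id: str
    true_type: int
    true_subtype: Optional[str]
    true_physician_id: Optional[str]


@dataclass
class SimulatedData:
    patients: List[PatientProfile] = field(default_factory=list)
    physicians: List[PhysicianProfile] = field(default_factory=list)
    spells: List[EnrolmentSpell] = field(default_factory=list)
    visits: List[VisitRecord] = field(default_factory=list)
    truth: List[TruthRow] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        claims_io.write_patients(out_dir / "patients.csv", self.patients)
        claims_io.write_physicians(out_dir / "physicians.csv", self.physicians)
        claims_io.write_visits(out_dir / "visits.csv", self.visits)
        claims_io.write_enrolment(out_dir / "enrolment.csv", self.spells)
        write_truth(out_dir / "truth.csv", self.truth)


def write_truth(path, truth: Sequence[TruthRow]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "true_type", "true_subtype", "true_physician_id"])
        for row in truth:
            writer.writerow(
                [row.patient_id, str(row.true_type), row.true_subtype or "",
                 row.true_physician_id or ""]
            )


def read_truth(path) -> List[TruthRow]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)
        return [
            TruthRow(r[0], int(r[1]), r[2] or None, r[3] or None) for r in reader
        ]


# ---------------------------------------------------------------------------
# deterministic single-patient fixtures

def _profile(pid: str) -> PatientProfile:
    return PatientProfile(
        patient_id=pid, birth_date=dt.date(1970, 1, 1), sex="F",
        resident_flag=True, long_term_care_flag=False, death_date=None,
        diabetes_flag=False, morbidity_band="low",
    )


def fixture_physicians() -> List[PhysicianProfile]:
    """Roster assumed by :func:`make_fixture`: three fee-for-service clinicians."""
    return [
        PhysicianProfile(pid, "fee_for_service", "phc_clinic")
        for pid in ("P1", "P2", "P3")
    ]


def _visit(pid, doc, day, *, setting="phc_clinic", act="visit") -> VisitRecord:
    return VisitRecord(pid, doc, day, setting, act)


def make_fixture(
    type_id, variant: str = "generic", window: StudyWindow = DEFAULT_WINDOW
) -> Tuple[PatientProfile, List[EnrolmentSpell], List[VisitRecord]]:
    """Build one minimal patient whose records realise exactly one type.

    ``variant`` is ``"generic"`` or ``"boundary"``; boundary constructions
    sit exactly on the rule thresholds (548 enrolment days; UPC exactly
    3/4; CMEs in consecutive calendar years; UPC exactly 1/2 for 8d).
    Physician ids refer to :func:`fixture_physicians`.
    """
    code = str(type_id)
    if code not in FIXTURE_TYPES:
        raise InvalidInputError(f"unknown fixture type {type_id!r}")
    if variant not in {"generic", "boundary"}:
        raise InvalidInputError(f"unknown variant {variant!r}")
    boundary = variant == "boundary"
    pid = f"FX{code}{'b' if boundary else 'g'}"
    patient = _profile(pid)
    ws = window.start_date
    spells: List[EnrolmentSpell] = []
    visits: List[VisitRecord] = []

    def qual_spell(doc: str, kind: str) -> EnrolmentSpell:
        if boundary:
            end = ws + dt.timedelta(days=window.min_enrolment_days - 1)
        else:
            end = ws + dt.timedelta(days=window.min_enrolment_days + 60)
        return EnrolmentSpell(pid, doc, kind, ws, end)

    if code == "1":
        spells.append(qual_spell("P1", "fmg"))
        visits += [_visit(pid, "P1", ws + dt.timedelta(days=d)) for d in (30, 200)]
        return patient, spells, visits
    if code == "2":
        spells.append(qual_spell("P1", "vulnerable"))
        visits += [_visit(pid, "P1", ws + dt.timedelta(days=d)) for d in (30, 200)]
        return patient, spells, visits
    if code == "3":
        if boundary:  # consecutive calendar years, minimal gap across Jan 1
            days = [dt.date(2009, 2, 1), dt.date(2010, 2, 1)]
        else:
            days = [dt.date(2008, 6, 15), dt.date(2009, 6, 20)]
        visits += [_visit(pid, "P1", d, act="cme") for d in days]
        visits.append(_visit(pid, "P1", dt.date(2009, 9, 1)))
        return patient, spells, visits
    if code == "4":
        visits.append(_visit(pid, "P1", dt.date(2008, 10, 10), act="cme"))
        if boundary:  # share to P1 exactly 3/4
            visits += [_visit(pid, "P1", dt.date(2009, m, 5)) for m in (2, 6)]
            visits.append(_visit(pid, "P2", dt.date(2009, 8, 5)))
        else:  # share 5/6
            visits += [_visit(pid, "P1", dt.date(2009, m, 5)) for m in (1, 3, 5, 7)]
            visits.append(_visit(pid, "P2", dt.date(2009, 9, 5)))
        return patient, spells, visits
    if code == "5":
        visits.append(_visit(pid, "P1", dt.date(2008, 10, 10), act="cme"))
        if boundary:  # share to CME physician 2/3, just under 3/4
            visits.append(_visit(pid, "P1", dt.date(2009, 2, 5)))
            visits.append(_visit(pid, "P2", dt.date(2009, 6, 5)))
        else:  # share 1/4
            visits += [_visit(pid, "P2", dt.date(2009, m, 5)) for m in (2, 4, 6)]
        return patient, spells, visits
    if code == "6":
        if boundary:  # UPC exactly 3/4
            split = [("P1", 3), ("P2", 1)]
        else:  # 5/6
            split = [("P1", 5), ("P2", 1)]
        month = 1
        for doc, k in split:
            for _ in range(k):
                visits.append(_visit(pid, doc, dt.date(2009, month, 10)))
                month += 1
        return patient, spells, visits
    if code == "7":
        visits.append(_visit(pid, "P1", dt.date(2009, 5, 5)))
        visits.append(_visit(pid, "P2", dt.date(2009, 7, 1), setting="emergency_room"))
        return patient, spells, visits
    if code == "8a":
        if boundary:  # two 547-day spells, one day short of qualifying, each
            spells.append(EnrolmentSpell(
                pid, "P1", "fmg", ws,
                ws + dt.timedelta(days=window.min_enrolment_days - 2)))
            spells.append(EnrolmentSpell(
                pid, "P2", "vulnerable",
                window.end_date - dt.timedelta(days=window.min_enrolment_days - 2),
                window.end_date))
        else:
            spells.append(EnrolmentSpell(
                pid, "P1", "fmg", dt.date(2008, 5, 1), dt.date(2008, 12, 31)))
            spells.append(EnrolmentSpell(
                pid, "P2", "vulnerable", dt.date(2009, 2, 1), dt.date(2009, 9, 30)))
        visits.append(_visit(pid, "P1", dt.date(2008, 7, 1)))
        visits.append(_visit(pid, "P2", dt.date(2009, 5, 1)))
        return patient, spells, visits
    if code == "8b":
        visits.append(_visit(pid, "P1", dt.date(2008, 7, 1), act="cme"))
        visits.append(_visit(pid, "P2", dt.date(2009, 7, 1), act="cme"))
        return patient, spells, visits
    if code == "8c":
        if boundary:  # UPC 2/3: smallest score strictly above 1/2 and below 3/4
            split = [("P1", 2), ("P2", 1)]
        else:  # 6/10
            split = [("P1", 6), ("P2", 4)]
        day = 0
        for doc, k in split:
            for _ in range(k):
                visits.append(_visit(pid, doc, ws + dt.timedelta(days=30 + day * 20)))
                day += 1
        return patient, spells, visits
    if code in {"8d", "8"}:
        if boundary:  # UPC exactly 1/2 at the minimal two visits
            split = [("P1", 1), ("P2", 1)]
        else:
            split = [("P1", 2), ("P2", 2)]
        day = 0
        for doc, k in split:
            for _ in range(k):
                visits.append(_visit(pid, doc, ws + dt.timedelta(days=40 + day * 25)))
                day += 1
        return patient, spells, visits
    # 8e: active user (emergency-room record) with no clinic visit at all
    visits.append(_visit(pid, "P1", dt.date(2009, 1, 15), setting="emergency_room"))
    if not boundary:
        visits.append(
            _visit(pid, "P2", dt.date(2009, 3, 2), setting="hospital_inpatient"))
    return patient, spells, visits


def fixture_truth(type_id) -> Tuple[int, Optional[str], Optional[str]]:
    """Expected (type, subtype, attached physician) for a fixture patient."""
    code = str(type_id)
    if code in {"1", "2", "3", "4", "5", "6", "7"}:
        return int(code), None, "P1"
    if code == "8":
        return 8, "8d", None
    return 8, code, None


# ---------------------------------------------------------------------------
# population simulation

def _rand_window_date(rng, window: StudyWindow) -> dt.date:
    return window.start_date + dt.timedelta(days=int(rng.integers(0, window.length_days)))


def _rand_date_in_year(rng, year: int, window: StudyWindow) -> dt.date:
    lo = max(dt.date(year, 1, 1), window.start_date)
    hi = min(dt.date(year, 12, 31), window.end_date)
    span = (hi - lo).days + 1
    return lo + dt.timedelta(days=int(rng.integers(0, span)))


def _qualifying_spell(rng, pid, doc, kind, window: StudyWindow) -> EnrolmentSpell:
    length = int(rng.integers(window.min_enrolment_days, window.length_days + 1))
    off = int(rng.integers(0, window.length_days - length + 1))
    start = window.start_date + dt.timedelta(days=off)
    return EnrolmentSpell(pid, doc, kind, start, start + dt.timedelta(days=length - 1))


def _short_spell(rng, pid, doc, kind, window: StudyWindow) -> EnrolmentSpell:
    length = int(rng.integers(60, window.min_enrolment_days))
    off = int(rng.integers(0, window.length_days - length + 1))
    start = window.start_date + dt.timedelta(days=off)
    return EnrolmentSpell(pid, doc, kind, start, start + dt.timedelta(days=length - 1))


def _n_visits(rng, mean: float, minimum: int) -> int:
    return max(minimum, int(rng.poisson(mean)))


def _others(rng, pool: List[str], exclude: set, k: int) -> List[str]:
    avail = [p for p in pool if p not in exclude]
    idx = rng.choice(len(avail), size=min(k, len(avail)), replace=False)
    return [avail[i] for i in np.atleast_1d(idx)]


def _spread(rng, pid, docs: List[str], k: int, window) -> List[VisitRecord]:
    """k ordinary visits spread round-robin over the given physicians."""
    return [
        _visit(pid, docs[i % len(docs)], _rand_window_date(rng, window))
        for i in range(k)
    ]


def _cme_year_pair(rng, window: StudyWindow) -> Tuple[int, int]:
    years = sorted({window.start_date.year, window.end_date.year}
                   | set(range(window.start_date.year, window.end_date.year + 1)))
    pairs = [(a, b) for i, a in enumerate(years) for b in years[i + 1:]]
    consec = [p for p in pairs if p[1] == p[0] + 1]
    if consec and rng.random() < 0.9:
        pairs = consec
    return pairs[int(rng.integers(0, len(pairs)))]


def _make_physicians(cfg: SimulationConfig, rng) -> Tuple[
        List[PhysicianProfile], List[str], List[str]]:
    physicians: List[PhysicianProfile] = []
    ffs: List[str] = []
    for i in range(cfg.n_physicians):
        pid = f"D{i + 1:04d}"
        if rng.random() < cfg.time_basis_fraction:
            setting = ("community_health_centre" if rng.random() < 0.5
                       else "teaching_unit")
            physicians.append(PhysicianProfile(pid, "time_basis", setting))
        else:
            physicians.append(PhysicianProfile(pid, "fee_for_service", "phc_clinic"))
            ffs.append(pid)
    if len(ffs) < 4:
        raise InvalidInputError("too few fee-for-service physicians; raise n_physicians")
    n_fmg = max(2, int(round(cfg.fmg_fraction * len(ffs))))
    fmg = ffs[:n_fmg]  # deterministic subset; membership has no billing signature
    return physicians, ffs, fmg


_TYPE_AGE_WEIGHTS = {
    2: (0.05, 0.15, 0.30, 0.50),
    7: (0.60, 0.20, 0.13, 0.07),
    8: (0.55, 0.25, 0.13, 0.07),
}
_TYPE_DIABETES = {2: 0.28, 7: 0.03, 8: 0.05}
_TYPE_MORBIDITY = {
    2: (0.10, 0.45, 0.45),
    7: (0.60, 0.35, 0.05),
    8: (0.60, 0.35, 0.05),
}


def _demographics(rng, pid: str, true_type: int, cfg: SimulationConfig) -> PatientProfile:
    if cfg.covariate_gradients:
        age_w = _TYPE_AGE_WEIGHTS.get(true_type, _BASE_AGE_WEIGHTS)
        p_diab = _TYPE_DIABETES.get(true_type, 0.08)
        morb_w = _TYPE_MORBIDITY.get(true_type, _BASE_MORBIDITY)
    else:
        age_w, p_diab, morb_w = _BASE_AGE_WEIGHTS, 0.093, _BASE_MORBIDITY
    band = _AGE_BANDS[int(rng.choice(4, p=np.asarray(age_w) / sum(age_w)))]
    age = int(rng.integers(band[0], band[1] + 1))
    birth = cfg.window.start_date - dt.timedelta(
        days=int(age * 365.25) + int(rng.integers(1, 360)))
    morb = ("low", "moderate", "high")[
        int(rng.choice(3, p=np.asarray(morb_w) / sum(morb_w)))]
    return PatientProfile(
        patient_id=pid,
        birth_date=birth,
        sex="F" if rng.random() < 0.551 else "M",
        resident_flag=True,
        long_term_care_flag=False,
        death_date=None,
        diabetes_flag=bool(rng.random() < p_diab),
        morbidity_band=morb,
    )


def _realize(
    rng, pid: str, code: str, cfg: SimulationConfig,
    ffs: List[str], fmg: List[str],
) -> Tuple[List[EnrolmentSpell], List[VisitRecord], Optional[str]]:
    """Generate records satisfying exactly the target type's predicate."""
    window = cfg.window
    mean = cfg.mean_visits
    spells: List[EnrolmentSpell] = []
    visits: List[VisitRecord] = []

    def pick(pool: List[str]) -> str:
        return pool[int(rng.integers(0, len(pool)))]

    if code == "1":
        doc = pick(fmg)
        spells.append(_qualifying_spell(rng, pid, doc, "fmg", window))
        if rng.random() < 0.35:
            spells.append(_qualifying_spell(rng, pid, doc, "vulnerable", window))
        if rng.random() < 0.2:
            visits.append(_visit(pid, doc, _rand_window_date(rng, window), act="cme"))
        for _ in range(_n_visits(rng, mean, 1)):
            target = doc if rng.random() < 0.6 else pick(ffs)
            visits.append(_visit(pid, target, _rand_window_date(rng, window)))
        return spells, visits, doc
    if code == "2":
        doc = pick(ffs)
        spells.append(_qualifying_spell(rng, pid, doc, "vulnerable", window))
        for _ in range(_n_visits(rng, mean, 1)):
            target = doc if rng.random() < 0.75 else pick(ffs)
            visits.append(_visit(pid, target, _rand_window_date(rng, window)))
        return spells, visits, doc
    if code == "3":
        doc = pick(ffs)
        y1, y2 = _cme_year_pair(rng, window)
        visits.append(_visit(pid, doc, _rand_date_in_year(rng, y1, window), act="cme"))
        visits.append(_visit(pid, doc, _rand_date_in_year(rng, y2, window), act="cme"))
        for _ in range(_n_visits(rng, max(mean - 2, 0.5), 0)):
            target = doc if rng.random() < 0.6 else pick(ffs)
            visits.append(_visit(pid, target, _rand_window_date(rng, window)))
        return spells, visits, doc
    if code in {"4", "5"}:
        doc = pick(ffs)
        n = _n_visits(rng, mean, 2)
        lo_attached = -(-3 * n // 4)  # ceil(3n/4): minimal count meeting 75%
        if code == "4":
            v_doc = int(rng.integers(lo_attached, n + 1))
        else:
            v_doc = int(rng.integers(1, (3 * n - 1) // 4 + 1))
        year = int(rng.integers(window.start_date.year, window.end_date.year + 1))
        visits.append(_visit(pid, doc, _rand_date_in_year(rng, year, window), act="cme"))
        visits += _spread(rng, pid, [doc], v_doc - 1, window)
        visits += _spread(rng, pid, _others(rng, ffs, {doc}, 2), n - v_doc, window)
        return spells, visits, doc
    if code == "6":
        doc = pick(ffs)
        n = _n_visits(rng, mean, 2)
        modal = int(rng.integers(-(-3 * n // 4), n + 1))
        visits += _spread(rng, pid, [doc], modal, window)
        visits += _spread(rng, pid, _others(rng, ffs, {doc}, 2), n - modal, window)
        return spells, visits, doc
    if code == "7":
        doc = pick(ffs)
        visits.append(_visit(pid, doc, _rand_window_date(rng, window)))
        if rng.random() < 0.5:
            visits.append(_visit(pid, pick(ffs), _rand_window_date(rng, window),
                                 setting="emergency_room"))
        return spells, visits, doc
    if code == "8a":
        d1 = pick(ffs)
        d2 = _others(rng, ffs, {d1}, 1)[0]
        spells.append(_short_spell(rng, pid, d1, "fmg" if rng.random() < 0.5
                                   else "vulnerable", window))
        spells.append(_short_spell(rng, pid, d2, "vulnerable", window))
        n = _n_visits(rng, mean, 2)
        visits += _spread(rng, pid, [d1, d2] + _others(rng, ffs, {d1, d2}, 1), n, window)
        return spells, visits, None
    if code == "8b":
        d1 = pick(ffs)
        d2 = _others(rng, ffs, {d1}, 1)[0]
        for doc in (d1, d2):
            year = int(rng.integers(window.start_date.year, window.end_date.year + 1))
            visits.append(_visit(pid, doc, _rand_date_in_year(rng, year, window),
                                 act="cme"))
        visits += _spread(rng, pid, [d1, d2], _n_visits(rng, max(mean - 2, 0.5), 0),
                          window)
        return spells, visits, None
    if code == "8c":
        doc = pick(ffs)
        n = _n_visits(rng, mean, 3)
        if n == 4:  # no integer count gives a score strictly between 1/2 and 3/4
            n = 5
        m_low = n // 2 + 1
        m_high = (3 * n - 1) // 4
        modal = int(rng.integers(m_low, m_high + 1))
        visits += _spread(rng, pid, [doc], modal, window)
        visits += _spread(rng, pid, _others(rng, ffs, {doc}, 2), n - modal, window)
        return spells, visits, None
    if code == "8d":
        docs = _others(rng, ffs, set(), 3)
        visits += _spread(rng, pid, docs, _n_visits(rng, mean, 2), window)
        return spells, visits, None
    # 8e: activity only outside primary-care clinics
    for _ in range(_n_visits(rng, 1.0, 1)):
        setting = "emergency_room" if rng.random() < 0.7 else "hospital_inpatient"
        visits.append(_visit(pid, pick(ffs), _rand_window_date(rng, window),
                             setting=setting))
    return spells, visits, None


def simulate(config: SimulationConfig) -> SimulatedData:
    """Draw a population from the type mixture; classification truth is exact
    by construction and returned in the truth table."""
    rng = np.random.default_rng(config.seed)
    data = SimulatedData()
    physicians, ffs, fmg = _make_physicians(config, rng)
    data.physicians = physicians

    mixture = np.asarray(config.type_mixture, dtype=float)
    subsplit = np.asarray(config.subtype_split, dtype=float)
    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        true_type = int(rng.choice(8, p=mixture)) + 1
        subtype = None
        code = str(true_type)
        if true_type == 8:
            subtype = ("8a", "8b", "8c", "8d", "8e")[int(rng.choice(5, p=subsplit))]
            code = subtype
        data.patients.append(_demographics(rng, pid, true_type, config))
        spells, visits, attached = _realize(rng, pid, code, config, ffs, fmg)
        # background emergency-room contact, invisible to the clinic rules
        if code not in {"7", "8e"} and rng.random() < 0.15:
            visits.append(_visit(pid, ffs[int(rng.integers(0, len(ffs)))],
                                 _rand_window_date(rng, config.window),
                                 setting="emergency_room"))
        data.spells += spells
        data.visits += visits
        data.truth.append(TruthRow(pid, true_type, subtype, attached))
    return data


def plant_violations(
    visits: Sequence[VisitRecord], rate: float, seed: int
) -> Tuple[List[VisitRecord], List[VisitRecord]]:
    """Inject duplicate same-year CME billings at the given per-CME rate.

    Returns the augmented visit list and the injected rows, so a caller can
    assert the validator flags exactly as many rows as were injected.
    Duplicates are dated one day after the original (one day before when
    the original sits on the last billable day of its year).
    """
    if not 0 <= rate <= 1:
        raise InvalidInputError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(visits)
    injected: List[VisitRecord] = []
    for v in visits:
        if v.act != "cme" or rng.random() >= rate:
            continue
        later = v.service_date + dt.timedelta(days=1)
        if later.year != v.service_date.year:
            later = v.service_date - dt.timedelta(days=1)
        dup = replace(v, service_date=later)
        out.append(dup)
        injected.append(dup)
    return out, injected
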