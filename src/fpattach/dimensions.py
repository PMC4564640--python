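"""Per-patient attachment dimensions: enrolment, CME history, visit concentration.

Three independent facts feed the classification cascade:

* **Qualifying enrolment** — a physician with whom the patient has been
  enrolled (family-medicine-group or vulnerable-patient enrolment) for at
  least ``min_enrolment_days`` within the window, merging overlapping
  spells per (physician, kind).
* **CME history** — complete medical examinations billed in a primary-care
  clinic by fee-for-service physicians: a same-physician pair (two CMEs in
  distinct calendar years), a single CME, or CMEs spread across
  physicians.
* **UPC concentration** — the usual-provider-of-care score: the fraction
  of primary-care-clinic visits made to the most frequently seen
  fee-for-service physician, defined only for patients with two or more
  such visits.  Threshold comparisons are exact rational arithmetic
  (``4 * modal >= 3 * total`` for the 75% rule), never floating point.

Physicians paid on a time basis (community health centres, teaching units)
do not generate fee-for-service claims, so their activity is invisible to
the CME and UPC computations; their enrolments still count.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .model import (
    EnrolmentSpell,
    PhysicianProfile,
    StudyWindow,
    VisitRecord,
    overlap_days,
)


@dataclass
class EnrolmentStatus:
    fmg_physician_id: Optional[str] = None
    vulnerable_physician_id: Optional[str] = None
    any_enrolment_flag: bool = False
    multi_physician_flag: bool = False


@dataclass
class CmeStatus:
    cme_events: List[Tuple[str, dt.date]] = field(default_factory=list)
    same_physician_pair: Optional[str] = None
    single_cme_physician: Optional[str] = None
    multi_physician_cme_flag: bool = False


@dataclass
class UpcResult:
    n_countable_visits: int = 0
    modal_physician_id: Optional[str] = None
    modal_count: int = 0
    upc_score: Optional[Fraction] = None
    share_to: Dict[str, Fraction] = field(default_factory=dict)


def _merged_overlap_days(spells: List[EnrolmentSpell], window: StudyWindow) -> int:
    """Total window days covered by the union of the spells (closed intervals)."""
    clipped = []
    for s in spells:
        end = s.end_date if s.end_date is not None else window.end_date
        lo = max(s.start_date, window.start_date)
        hi = min(end, window.end_date)
        if hi >= lo:
            clipped.append((lo, hi))
    if not clipped:
        return 0
    clipped.sort()
    total = 0
    cur_lo, cur_hi = clipped[0]
    for lo, hi in clipped[1:]:
        if lo <= cur_hi + dt.timedelta(days=1):
            cur_hi = max(cur_hi, hi)
        else:
            total += (cur_hi - cur_lo).days + 1
            cur_lo, cur_hi = lo, hi
    total += (cur_hi - cur_lo).days + 1
    return total


def qualify_enrolment(
    spells: Iterable[EnrolmentSpell], window: StudyWindow
) -> EnrolmentStatus:
    """Resolve one patient's spells into a qualifying-enrolment status.

    Per (physician, kind), overlapping spells are merged and their
    window-overlap days summed; the physician qualifies for that kind when
    the sum reaches ``window.min_enrolment_days``.  Ties between several
    qualifying physicians of the same kind are broken by most days, then
    earliest spell start, then smallest physician id.
    """
    spells = list(spells)
    status = EnrolmentStatus()
    if not spells:
        return status
    status.any_enrolment_flag = any(overlap_days(s, window) > 0 for s in spells)

    by_key: Dict[Tuple[str, str], List[EnrolmentSpell]] = defaultdict(list)
    for s in spells:
        by_key[(s.physician_id, s.kind)].append(s)

    best: Dict[str, Tuple[int, dt.date, str]] = {}
    for (physician_id, kind), group in by_key.items():
        days = _merged_overlap_days(group, window)
        if days < window.min_enrolment_days:
            continue
        earliest = min(s.start_date for s in group)
        cand = (-days, earliest, physician_id)
        if kind not in best or cand < best[kind]:
            best[kind] = cand
    if "fmg" in best:
        status.fmg_physician_id = best["fmg"][2]
    if "vulnerable" in best:
        status.vulnerable_physician_id = best["vulnerable"][2]

    if status.fmg_physician_id is None and status.vulnerable_physician_id is None:
        physicians = {s.physician_id for s in spells if overlap_days(s, window) > 0}
        status.multi_physician_flag = len(physicians) >= 2
    return status


def _payment_lookup(
    physicians: Mapping[str, PhysicianProfile] | Iterable[PhysicianProfile],
) -> Dict[str, str]:
    if isinstance(physicians, Mapping):
        return {
            pid: (prof.payment_mode if isinstance(prof, PhysicianProfile) else prof)
            for pid, prof in physicians.items()
        }
    return {p.physician_id: p.payment_mode for p in physicians}


def _countable(
    visits: Iterable[VisitRecord],
    payment_mode: Dict[str, str],
    window: StudyWindow,
) -> List[VisitRecord]:
    """Claim rows that enter CME/UPC: in-window, clinic setting, fee-for-service.

    A physician absent from the roster is assumed fee-for-service (claims
    only exist for fee-for-service activity in the first place).
    """
    return [
        v
        for v in visits
        if window.contains(v.service_date)
        and v.setting == "phc_clinic"
        and payment_mode.get(v.physician_id, "fee_for_service") == "fee_for_service"
    ]


def detect_cme(
    visits: Iterable[VisitRecord],
    physicians: Mapping[str, PhysicianProfile] | Iterable[PhysicianProfile],
    window: StudyWindow,
) -> CmeStatus:
    """Summarise one patient's complete-medical-examination billing history.

    ``same_physician_pair`` is the physician with two or more CMEs for the
    patient (necessarily in distinct calendar years, the billing rule
    allowing one per year); ties go to more CMEs, then the most recent CME,
    then the smallest id.  ``single_cme_physician`` is set when exactly one
    CME exists in total.  ``multi_physician_cme_flag`` marks patients whose
    several CMEs are spread over several physicians with no pair.
    """
    payment = _payment_lookup(physicians)
    status = CmeStatus()
    events = [
        (v.physician_id, v.service_date)
        for v in _countable(visits, payment, window)
        if v.act == "cme"
    ]
    events.sort(key=lambda e: (e[1], e[0]))
    status.cme_events = events
    if not events:
        return status

    per_physician: Dict[str, List[dt.date]] = defaultdict(list)
    for pid, day in events:
        per_physician[pid].append(day)

    pairs = [
        (-len(days), -max(days).toordinal(), pid)
        for pid, days in per_physician.items()
        if len(days) >= 2
    ]
    if pairs:
        status.same_physician_pair = min(pairs)[2]
    elif len(events) == 1:
        status.single_cme_physician = events[0][0]
    else:  # >= 2 CMEs, all singletons, hence >= 2 physicians
        status.multi_physician_cme_flag = True
    return status


def compute_upc(
    visits: Iterable[VisitRecord],
    physicians: Mapping[str, PhysicianProfile] | Iterable[PhysicianProfile],
    window: StudyWindow,
    *,
    cme_counts_as_visit: bool = True,
) -> UpcResult:
    """Usual-provider-of-care concentration for one patient.

    Countable visits are in-window clinic claims by fee-for-service
    physicians; CME claims count as visits by default.  The modal physician
    maximises the visit count, ties broken by most recent visit date, then
    smallest physician id.  ``upc_score`` is undefined (None) below two
    countable visits.
    """
    payment = _payment_lookup(physicians)
    rows = _countable(visits, payment, window)
    if not cme_counts_as_visit:
        rows = [v for v in rows if v.act != "cme"]

    result = UpcResult(n_countable_visits=len(rows))
    if not rows:
        return result

    counts: Dict[str, int] = defaultdict(int)
    latest: Dict[str, dt.date] = {}
    for v in rows:
        counts[v.physician_id] += 1
        if v.physician_id not in latest or v.service_date > latest[v.physician_id]:
            latest[v.physician_id] = v.service_date

    n = len(rows)
    result.share_to = {pid: Fraction(c, n) for pid, c in counts.items()}
    modal = min(
        counts, key=lambda pid: (-counts[pid], -latest[pid].toordinal(), pid)
    )
    result.modal_physician_id = modal
    result.modal_count = counts[modal]
    if n >= 2:
        result.upc_score = Fraction(counts[modal], n)
    return result


def share_to_physician(upc: UpcResult, physician_id: str) -> Optional[Fraction]:
    """Fraction of countable visits made to the given physician.

    Mirrors the UPC domain: None when fewer than two countable visits,
    0 for a physician never seen.
    """
    if upc.n_countable_visits < 2:
        return None
    return upc.share_to.get(physician_id, Fraction(0))


@dataclass
class DimensionTables:
    """Per-patient dimension results for a whole cohort."""

    enrolment: Dict[str, EnrolmentStatus]
    cme: Dict[str, CmeStatus]
    upc: Dict[str, UpcResult]


def compute_dimensions(
    patient_ids: Iterable[str],
    visits: Iterable[VisitRecord],
    spells: Iterable[EnrolmentSpell],
    physicians: Iterable[PhysicianProfile],
    window: StudyWindow,
    *,
    cme_counts_as_visit: bool = True,
) -> DimensionTables:
    """Compute all three dimensions for every listed patient."""
    payment = _payment_lookup(physicians)
    visits_by_patient: Dict[str, List[VisitRecord]] = defaultdict(list)
    for v in visits:
        visits_by_patient[v.patient_id].append(v)
    spells_by_patient: Dict[str, List[EnrolmentSpell]] = defaultdict(list)
    for s in spells:
        spells_by_patient[s.patient_id].append(s)

    tables = DimensionTables({}, {}, {})
    for pid in patient_ids:
        pv = visits_by_patient.get(pid, [])
        tables.enrolment[pid] = qualify_enrolment(spells_by_patient.get(pid, []), window)
        tables.cme[pid] = detect_cme(pv, payment, window)
        tables.upc[pid] = compute_upc(
            pv, payment, window, cme_counts_as_visit=cme_counts_as_visit
        )
    return tables
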