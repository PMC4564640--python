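"""Hierarchical cascade assigning one attachment type per patient.

The cascade walks the three dimensions from strongest to weakest evidence
of a patient-physician bond and stops at the first rule that fires:

1. enrolled with a family-medicine-group physician (>= 18 months);
2. else enrolled as a vulnerable patient (>= 18 months);
3. else two complete medical examinations (CMEs) by the same physician;
4. else one CME with >= 75% of visits concentrated on the CME physician;
5. else one CME;
6. else usual-provider-of-care (UPC) score >= 75%;
7. else a single non-CME clinic visit;
8. else non-attached, optionally refined into subtypes 8a-8e.

Patients whose several CMEs are spread over different physicians satisfy
none of rules 3-5; by default they go straight to type 8 (they form their
own non-attached subtype, 8b), a routing that can be relaxed to let them
compete at rule 6.

Types 1-7 name the attached physician; type 8 never does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Tuple

from .cohort import Cohort
from .dimensions import (
    CmeStatus,
    DimensionTables,
    EnrolmentStatus,
    UpcResult,
    share_to_physician,
)
from .model import AttachmentResult, InvalidInputError

log = logging.getLogger(__name__)


class InternalConsistencyError(RuntimeError):
    """Dimension inputs contradict each other (or a patient is missing)."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable rules of the cascade.

    ``strict_no_enrolment`` reads "without any type of enrolment" literally:
    any spell touching the window — even one too short to qualify — blocks
    rules 3-7.  Default off, since the non-attached taxonomy has no slot for
    short-spell patients and blocking would leave them undescribed.

    ``multi_cme_to_type8`` routes patients with CMEs by several physicians
    (and no same-physician pair) directly to type 8 instead of letting them
    compete at the concentration rule.
    """

    strict_no_enrolment: bool = False
    multi_cme_to_type8: bool = True
    upc_threshold: Fraction = Fraction(3, 4)
    upc_partial_band: Tuple[Fraction, Fraction] = (Fraction(51, 100), Fraction(74, 100))

    def __post_init__(self) -> None:
        low, high = self.upc_partial_band
        if not (0 < low < high < self.upc_threshold <= 1):
            raise InvalidInputError(
                "require 0 < band.low < band.high < upc_threshold <= 1"
            )


DEFAULT_CONFIG = ClassifierConfig()


def _dimension_flags(
    enrolment: EnrolmentStatus, cme: CmeStatus, upc: UpcResult, cfg: ClassifierConfig
) -> frozenset:
    flags = set()
    if enrolment.fmg_physician_id is not None:
        flags.add("fmg_enrolled")
    if enrolment.vulnerable_physician_id is not None:
        flags.add("vulnerable_enrolled")
    if cme.same_physician_pair is not None:
        flags.add("two_cme")
    if cme.single_cme_physician is not None:
        flags.add("one_cme")
    if upc.upc_score is not None and upc.upc_score >= cfg.upc_threshold:
        flags.add("upc_ge_75")
    if upc.n_countable_visits == 1 and not cme.cme_events:
        flags.add("single_visit")
    return frozenset(flags)


def subtype_nonattached(
    enrolment: EnrolmentStatus,
    cme: CmeStatus,
    upc: UpcResult,
) -> str:
    """Refine a non-attached (type 8) patient into subtypes 8a-8e.

    First matching row wins:

    * 8a — enrolment spells with different physicians, none qualifying;
    * 8b — several CMEs by different physicians;
    * 8c — UPC score above 50% (but below the 75% attachment threshold);
    * 8d — more than one clinic visit, UPC at or below 50%;
    * 8e — no countable ambulatory visit to a family physician.

    A type-8 patient matching no row (possible only under non-default
    configurations, e.g. an enrolment-blocked single visit) is folded into
    8d or 8e by visit count, with a warning.
    """
    if enrolment.multi_physician_flag:
        return "8a"
    if cme.multi_physician_cme_flag:
        return "8b"
    if upc.upc_score is not None and 2 * upc.upc_score > 1:
        return "8c"
    if upc.n_countable_visits >= 2:
        return "8d"
    if upc.n_countable_visits == 0:
        return "8e"
    log.warning(
        "non-attached patient matches no subtype row (n_countable=%d); "
        "assigning by visit count",
        upc.n_countable_visits,
    )
    return "8d"


def classify_patient(
    patient_id: str,
    enrolment: EnrolmentStatus,
    cme: CmeStatus,
    upc: UpcResult,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
    *,
    with_subtype: bool = True,
) -> AttachmentResult:
    """Run the cascade for one patient."""
    if cme.same_physician_pair is not None and cme.single_cme_physician is not None:
        raise InternalConsistencyError(
            f"{patient_id}: CME pair and single CME cannot both be set"
        )

    atype: int = 8
    physician: Optional[str] = None

    if enrolment.fmg_physician_id is not None:
        atype, physician = 1, enrolment.fmg_physician_id
    elif enrolment.vulnerable_physician_id is not None:
        atype, physician = 2, enrolment.vulnerable_physician_id
    elif not (cfg.strict_no_enrolment and enrolment.any_enrolment_flag):
        blocked_cme = cme.multi_physician_cme_flag
        if blocked_cme and cfg.multi_cme_to_type8:
            atype = 8
        elif not blocked_cme and cme.same_physician_pair is not None:
            atype, physician = 3, cme.same_physician_pair
        elif not blocked_cme and cme.single_cme_physician is not None:
            share = share_to_physician(upc, cme.single_cme_physician)
            if share is not None and share >= cfg.upc_threshold:
                atype, physician = 4, cme.single_cme_physician
            else:
                atype, physician = 5, cme.single_cme_physician
        elif upc.upc_score is not None and upc.upc_score >= cfg.upc_threshold:
            atype, physician = 6, upc.modal_physician_id
        elif upc.n_countable_visits == 1 and not cme.cme_events:
            atype, physician = 7, upc.modal_physician_id

    subtype = None
    if atype == 8 and with_subtype:
        subtype = subtype_nonattached(enrolment, cme, upc)

    return AttachmentResult(
        patient_id=patient_id,
        attachment_type=atype,
        subtype=subtype,
        attached_physician_id=physician,
        dimension_flags=_dimension_flags(enrolment, cme, upc, cfg),
        upc_score=upc.upc_score,
    )


def classify_records(
    patients,
    physicians,
    visits,
    spells,
    window,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
    *,
    cohort_kwargs: dict | None = None,
):
    """End-to-end convenience: cohort -> dimensions -> classification.

    Returns ``(cohort, dimension_tables, results)``.
    """
    from .cohort import build_cohort
    from .dimensions import compute_dimensions

    cohort = build_cohort(patients, visits, window, **(cohort_kwargs or {}))
    tables = compute_dimensions(
        cohort.eligible_patient_ids, visits, spells, physicians, window
    )
    return cohort, tables, classify_cohort(cohort, tables, cfg)


def classify_cohort(
    cohort: Cohort,
    tables: DimensionTables,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
) -> List[AttachmentResult]:
    """Classify every eligible patient; output sorted by patient id.

    Sorting makes the result independent of input row order.  A cohort
    patient missing from a dimension table is an internal error: dimensions
    must be computed for the full cohort first.
    """
    results = []
    for pid in sorted(cohort.eligible_patient_ids):
        try:
            enrolment = tables.enrolment[pid]
            cme = tables.cme[pid]
            upc = tables.upc[pid]
        except KeyError as exc:
            raise InternalConsistencyError(
                f"patient {pid} missing from dimension table"
            ) from exc
        results.append(classify_patient(pid, enrolment, cme, upc, cfg))
    if results:
        tally: Dict[int, int] = {}
        for r in results:
            tally[r.attachment_type] = tally.get(r.attachment_type, 0) + 1
        log.info(
            "classified %d patients: %s",
            len(results),
            {t: tally[t] for t in sorted(tally)},
        )
    return results
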