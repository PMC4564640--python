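"""Eligible study population: adult, resident, active health-services users.

A patient enters the cohort iff, in this order of evaluation:

1. aged 20 or over at the window start;
2. resident of the study territory (taken as a flag);
3. has at least one claim record of any setting dated inside the window
   ("active user" — emergency-room and hospital records count here even
   though they are excluded from the visit-concentration score);
4. not in a long-term-care facility;
5. not deceased on or before the window end (configurable).

A patient failing several criteria is tallied under the first failed
reason, so the exclusion tally is deterministic and sums with the eligible
count to the number of patients read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

from .model import PatientProfile, StudyWindow, VisitRecord, age_at

EXCLUSION_ORDER = ("age", "non_resident", "no_activity", "ltc", "deceased")


@dataclass
class Cohort:
    window: StudyWindow
    eligible_patient_ids: Set[str] = field(default_factory=set)
    exclusion_tally: Dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_ORDER}
    )

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_patient_ids)

    @property
    def n_total(self) -> int:
        return self.n_eligible + sum(self.exclusion_tally.values())


def build_cohort(
    patients: Iterable[PatientProfile],
    visits: Iterable[VisitRecord],
    window: StudyWindow,
    *,
    min_age: int = 20,
    exclude_death_within_window: bool = True,
) -> Cohort:
    """Apply the eligibility filter and return the cohort with exclusion tally.

    ``exclude_death_within_window`` controls whether a death date inside the
    window excludes the patient (default) or only a death before the window
    start does.
    """
    active: Set[str] = set()
    for v in visits:
        if window.contains(v.service_date):
            active.add(v.patient_id)

    cohort = Cohort(window=window)
    death_cutoff = window.end_date if exclude_death_within_window else window.start_date
    for p in patients:
        if p.birth_date > window.start_date or age_at(p, window.start_date) < min_age:
            cohort.exclusion_tally["age"] += 1
        elif not p.resident_flag:
            cohort.exclusion_tally["non_resident"] += 1
        elif p.patient_id not in active:
            cohort.exclusion_tally["no_activity"] += 1
        elif p.long_term_care_flag:
            cohort.exclusion_tally["ltc"] += 1
        elif p.death_date is not None and p.death_date <= death_cutoff:
            cohort.exclusion_tally["deceased"] += 1
        else:
            cohort.eligible_patient_ids.add(p.patient_id)
    return cohort


def cohort_summary_rows(cohort: Cohort) -> List[List[str]]:
    """Rows for the small reason,count summary CSV."""
    rows = [["eligible", str(cohort.n_eligible)]]
    rows += [[r, str(cohort.exclusion_tally[r])] for r in EXCLUSION_ORDER]
    return rows
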