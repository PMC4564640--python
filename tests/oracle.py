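"""Independent naive re-implementation used as a cross-check in tests.

Deliberately avoids the package's dimension/classifier code paths: day
counts come from explicit per-day set iteration, visit concentration from
a flat Counter, and the eight attachment-type definitions are tested as
independent predicates with the first true one winning.  Slow but
transparent.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter, defaultdict
from fractions import Fraction


def iter_days(start: dt.date, end: dt.date):
    d = start
    one = dt.timedelta(days=1)
    while d <= end:
        yield d
        d += one


def naive_age(birth: dt.date, reference: dt.date) -> int:
    """Count completed years by walking anniversaries."""
    years = 0
    while True:
        try:
            anniversary = birth.replace(year=birth.year + years + 1)
        except ValueError:  # Feb 29 -> Mar 1 in non-leap years
            anniversary = birth.replace(
                year=birth.year + years + 1, month=3, day=1)
        if anniversary > reference:
            return years
        years += 1


def naive_overlap_days(spell_start, spell_end, window) -> int:
    end = spell_end if spell_end is not None else window.end_date
    if end < spell_start:
        return 0
    spell_days = set(iter_days(spell_start, end))
    window_days = set(iter_days(window.start_date, window.end_date))
    return len(spell_days & window_days)


def _enrolment_day_sets(spells, window):
    days = defaultdict(set)
    for s in spells:
        end = s.end_date if s.end_date is not None else window.end_date
        for d in iter_days(s.start_date, end):
            if window.start_date <= d <= window.end_date:
                days[(s.physician_id, s.kind)].add(d)
    return days


def _best_qualifying(spells, window, kind):
    days = _enrolment_day_sets(spells, window)
    cands = []
    for (doc, k), ds in days.items():
        if k != kind or len(ds) < window.min_enrolment_days:
            continue
        earliest = min(s.start_date for s in spells
                       if s.physician_id == doc and s.kind == kind)
        cands.append((-len(ds), earliest, doc))
    return min(cands)[2] if cands else None


def _countable(visits, payment, window):
    return [
        v for v in visits
        if window.start_date <= v.service_date <= window.end_date
        and v.setting == "phc_clinic"
        and payment.get(v.physician_id, "fee_for_service") == "fee_for_service"
    ]


def naive_classify(patient_id, spells, visits, payment, window,
                   *, strict_no_enrolment=False, multi_cme_to_type8=True):
    """First-true-predicate classification: returns (type, subtype, physician)."""
    rows = _countable(visits, payment, window)
    cmes = [v for v in rows if v.act == "cme"]
    counts = Counter(v.physician_id for v in rows)
    n = len(rows)

    def share(doc):
        if n < 2:
            return None
        return Fraction(counts.get(doc, 0), n)

    def modal():
        latest = {}
        for v in rows:
            if v.physician_id not in latest or v.service_date > latest[v.physician_id]:
                latest[v.physician_id] = v.service_date
        return min(counts, key=lambda d: (-counts[d], -latest[d].toordinal(), d))

    cme_by_doc = Counter(v.physician_id for v in cmes)
    pair_docs = [d for d, c in cme_by_doc.items() if c >= 2]
    multi_cme = len(cmes) >= 2 and len(cme_by_doc) >= 2 and not pair_docs
    any_spell = any(
        naive_overlap_days(s.start_date, s.end_date, window) > 0 for s in spells
    )

    fmg = _best_qualifying(spells, window, "fmg")
    vul = _best_qualifying(spells, window, "vulnerable")

    # predicates in cascade order, each self-contained
    def p1():
        return fmg
    def p2():
        return vul
    def blocked():
        return (strict_no_enrolment and any_spell) or (multi_cme and multi_cme_to_type8)
    def p3():
        if blocked() or multi_cme or not pair_docs:
            return None
        latest = {d: max(v.service_date for v in cmes if v.physician_id == d)
                  for d in pair_docs}
        return min(pair_docs,
                   key=lambda d: (-cme_by_doc[d], -latest[d].toordinal(), d))
    def p4():
        if blocked() or multi_cme or len(cmes) != 1:
            return None
        doc = cmes[0].physician_id
        s = share(doc)
        return doc if s is not None and 4 * s.numerator >= 3 * s.denominator else None
    def p5():
        if blocked() or multi_cme or len(cmes) != 1:
            return None
        return cmes[0].physician_id
    def p6():
        if blocked() or n < 2:
            return None
        m = modal()
        return m if 4 * counts[m] >= 3 * n else None
    def p7():
        if blocked() or n != 1 or cmes:
            return None
        return rows[0].physician_id

    for t, pred in enumerate((p1, p2, p3, p4, p5, p6, p7), start=1):
        doc = pred()
        if doc is not None:
            return t, None, doc

    # non-attached subtype rows, first match wins
    enrolling = {s.physician_id for s in spells
                 if naive_overlap_days(s.start_date, s.end_date, window) > 0}
    if fmg is None and vul is None and len(enrolling) >= 2:
        sub = "8a"
    elif multi_cme:
        sub = "8b"
    elif n >= 2 and 2 * counts[modal()] > n:
        sub = "8c"
    elif n >= 2:
        sub = "8d"
    elif n == 0:
        sub = "8e"
    else:
        sub = "8d"
    return 8, sub, None
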