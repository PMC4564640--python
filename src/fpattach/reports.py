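"""Prevalence and stratification tables over classification results.

Five summary artifacts:

* :func:`type_distribution` — share of the cohort in each attachment type,
  with attached (types 1-7) and non-attached (type 8) aggregates;
* :func:`nonattached_breakdown` — the five non-attached subtypes 8a-8e as
  shares of the whole cohort;
* :func:`dimension_by_type` — prevalence of each underlying dimension flag
  within each type (flags are not exclusive, columns need not sum to 100);
* :func:`dimension_prevalence` — share of the cohort holding each
  dimension, each considered independently of the cascade;
* :func:`stratified_distribution` — the type distribution within strata of
  sex, age group, diabetes and morbidity band.

All tables are computed on exact counts; percentages are kept at full
precision in ``data`` and rounded half-up to one decimal only for display
(:meth:`PrevalenceTable.rounded`), matching the usual convention of
published prevalence tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .model import (
    DIMENSION_FLAGS,
    SUBTYPES,
    AttachmentResult,
    PatientProfile,
    StudyWindow,
    age_at,
)

TYPE_ROWS = [str(t) for t in range(1, 9)]

AGE_GROUPS = (("20-44", 20, 44), ("45-59", 45, 59), ("60-74", 60, 74), ("75+", 75, 200))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (12.25 -> 12.3), as printed tables round."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceTable:
    """Percentages at full precision plus the denominator behind each column."""

    data: pd.DataFrame
    denominators: Dict[str, int] = field(default_factory=dict)

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.data.map(
            lambda v: v if pd.isna(v) else round_half_up(v, decimals)
        )

    def to_csv(self, path, decimals: int = 1) -> None:
        out = self.rounded(decimals).copy()
        out.loc["_denominator"] = [
            self.denominators.get(c, float("nan")) for c in out.columns
        ]
        out.to_csv(path, index_label="row")


def _pct(count: int, denom: int) -> float:
    return 100.0 * count / denom


def type_distribution(results: Sequence[AttachmentResult]) -> PrevalenceTable:
    """One row per type 1-8 plus attached / non-attached aggregates (% of cohort)."""
    if not results:
        raise ValueError("cannot tabulate an empty result set")
    n = len(results)
    counts = {t: 0 for t in range(1, 9)}
    for r in results:
        counts[r.attachment_type] += 1
    rows = {str(t): _pct(counts[t], n) for t in range(1, 9)}
    rows["attached"] = _pct(sum(counts[t] for t in range(1, 8)), n)
    rows["non_attached"] = _pct(counts[8], n)
    df = pd.DataFrame({"all": rows})
    return PrevalenceTable(df, {"all": n})


def nonattached_breakdown(results: Sequence[AttachmentResult]) -> PrevalenceTable:
    """Subtypes 8a-8e as % of the whole cohort, with the non-attached total
    and the share of non-attached patients who saw a family physician more
    than once (8a-8d)."""
    if not results:
        raise ValueError("cannot tabulate an empty result set")
    n = len(results)
    counts = {s: 0 for s in SUBTYPES}
    for r in results:
        if r.attachment_type == 8:
            counts[r.subtype or "8d"] += 1
    rows = {s: _pct(counts[s], n) for s in SUBTYPES}
    rows["total"] = _pct(sum(counts.values()), n)
    rows["multi_visit_nonattached"] = _pct(
        sum(counts[s] for s in ("8a", "8b", "8c", "8d")), n
    )
    df = pd.DataFrame({"all": rows})
    return PrevalenceTable(df, {"all": n})


def dimension_by_type(results: Sequence[AttachmentResult]) -> PrevalenceTable:
    """For each type column, % of its patients holding each dimension flag.

    Flags are facts about the patient, not about which rule fired, so a
    type-1 patient may well also carry ``two_cme`` or ``upc_ge_75``.  A
    type with no patients yields a missing-marker (NaN) column.
    """
    if not results:
        raise ValueError("cannot tabulate an empty result set")
    by_type: Dict[int, List[AttachmentResult]] = {t: [] for t in range(1, 9)}
    for r in results:
        by_type[r.attachment_type].append(r)
    data: Dict[str, list] = {}
    denoms: Dict[str, int] = {}
    for t in range(1, 9):
        group = by_type[t]
        denoms[str(t)] = len(group)
        if not group:
            data[str(t)] = [float("nan")] * len(DIMENSION_FLAGS)
            continue
        data[str(t)] = [
            _pct(sum(1 for r in group if flag in r.dimension_flags), len(group))
            for flag in DIMENSION_FLAGS
        ]
    df = pd.DataFrame(data, index=list(DIMENSION_FLAGS))
    return PrevalenceTable(df, denoms)


def dimension_prevalence(results: Sequence[AttachmentResult]) -> PrevalenceTable:
    """% of the cohort holding each dimension, ignoring the cascade.

    Each row answers: how many users would count as attached if this
    dimension alone defined attachment?  Rows are not exclusive.
    """
    if not results:
        raise ValueError("cannot tabulate an empty result set")
    n = len(results)
    rows = {
        flag: _pct(sum(1 for r in results if flag in r.dimension_flags), n)
        for flag in DIMENSION_FLAGS
    }
    df = pd.DataFrame({"all": rows})
    return PrevalenceTable(df, {"all": n})


def stratified_distribution(
    results: Sequence[AttachmentResult],
    patients: Iterable[PatientProfile],
    window: StudyWindow,
) -> PrevalenceTable:
    """Type distribution within strata of sex, age group (at window start),
    diabetes, and morbidity band; every column sums to 100 up to rounding.
    """
    if not results:
        raise ValueError("cannot tabulate an empty result set")
    profile = {p.patient_id: p for p in patients}

    def strata_of(p: PatientProfile) -> List[str]:
        cols = ["all", "female" if p.sex == "F" else "male"]
        a = age_at(p, window.start_date)
        for label, lo, hi in AGE_GROUPS:
            if lo <= a <= hi:
                cols.append(f"age_{label}")
                break
        if p.diabetes_flag:
            cols.append("diabetes")
        cols.append(f"morbidity_{p.morbidity_band}")
        return cols

    columns = (
        ["all", "female", "male"]
        + [f"age_{label}" for label, _, _ in AGE_GROUPS]
        + ["diabetes", "morbidity_low", "morbidity_moderate", "morbidity_high"]
    )
    counts = {c: {t: 0 for t in range(1, 9)} for c in columns}
    denoms = {c: 0 for c in columns}
    for r in results:
        p = profile.get(r.patient_id)
        if p is None:
            raise KeyError(f"patient {r.patient_id} missing from patient file")
        for c in strata_of(p):
            counts[c][r.attachment_type] += 1
            denoms[c] += 1

    data: Dict[str, list] = {}
    index = TYPE_ROWS + ["attached", "non_attached"]
    for c in columns:
        n = denoms[c]
        if n == 0:
            data[c] = [float("nan")] * len(index)
            continue
        col = [_pct(counts[c][t], n) for t in range(1, 9)]
        col.append(_pct(sum(counts[c][t] for t in range(1, 8)), n))
        col.append(_pct(counts[c][8], n))
        data[c] = col
    df = pd.DataFrame(data, index=index)
    return PrevalenceTable(df, denoms)


def render_text(tables: Dict[str, PrevalenceTable]) -> str:
    """Plain-text rendering of named tables (display rounding applied)."""
    blocks = []
    for name, table in tables.items():
        df = table.rounded()
        blocks.append(f"== {name} ==\n{df.to_string(na_rep='-')}\n"
                      f"denominators: {table.denominators}")
    return "\n\n".join(blocks) + "\n"
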