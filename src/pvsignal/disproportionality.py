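"""Reporting-odds-ratio disproportionality screening.

For a term t (a MedDRA Preferred Term, or a System Organ Class after
aggregation) the case-level 2x2 table against a reference cohort is::

                 with t   without t
    index           a         b
    reference       c         d

The crude reporting odds ratio is ROR = (a*d)/(b*c), with a Woolf
(log-normal) 95% confidence interval
``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  A positive signal is
declared when the lower CI bound exceeds 1, a negative one when the upper
bound is below 1.  Any zero cell makes the ratio non-estimable; no
continuity correction is applied.

The screen runs each term against both the full reference cohort and the
time-normalized one; a term is "robust" when positive in both, the usual
guard against reporting-era artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .cohort import Cohort
from .model import ExpectedTerms, ICSR, MeddraMap

__all__ = [
    "Level",
    "Significance",
    "ContingencyTable",
    "SignalRow",
    "ScreenResult",
    "term_contingency",
    "ror_woolf",
    "screen",
    "annotate_expectedness",
]

Z_95 = 1.959964


class Level(Enum):
    PT = "pt"
    SOC = "soc"


class Significance(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"
    NOT_ESTIMABLE = "not_estimable"


@dataclass(frozen=True)
class ContingencyTable:
    """Case counts a/b/c/d for one term in one index-vs-reference comparison."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative cell {name}={v}")

    @property
    def n_index(self) -> int:
        return self.a + self.b

    @property
    def n_reference(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class SignalRow:
    """One screened term at one MedDRA level in one comparison."""

    term: str
    level: Level
    comparison: str  # "full" | "normalized"
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    significance: Significance
    expected: bool | None = None  # None = not applicable (SOC level)
    robust: bool = False

    @property
    def n_cases(self) -> int:
        return self.table.a


@dataclass(frozen=True)
class ScreenResult:
    rows: tuple[SignalRow, ...]
    reference_only: tuple[tuple[str, int], ...]  # (term, reference case count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([
            {
                "term": r.term,
                "level": r.level.value,
                "comparison": r.comparison,
                "n": r.n_cases,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "significance": r.significance.value,
                "expected": ("n/a" if r.expected is None
                             else ("Yes" if r.expected else "No")),
                "robust": "Yes" if r.robust else "No",
            }
            for r in self.rows
        ])


def _case_terms(icsr: ICSR, level: Level, meddra: MeddraMap | None) -> frozenset[str]:
    if level is Level.PT:
        return icsr.pts
    if level is Level.SOC:
        if meddra is None:
            raise ValueError("SOC-level counting requires a MedDRA map")
        return frozenset(meddra.soc_of(p) for p in icsr.pts)
    raise ValueError(f"unknown level {level!r}")


def _count_cases(cohort: Cohort, level: Level, meddra: MeddraMap | None) -> dict[str, int]:
    counts: dict[str, int] = {}
    for m in cohort.members:
        for t in _case_terms(m, level, meddra):
            counts[t] = counts.get(t, 0) + 1
    return counts


def term_contingency(
    index: Cohort,
    reference: Cohort,
    term: str,
    level: Level,
    meddra: MeddraMap | None = None,
) -> ContingencyTable:
    """Build the case-level 2x2 table for one term.

    A report counts in cell a (or c) when at least one of its reactions
    carries the PT (or maps to the SOC), and only once however many do.
    """
    if not isinstance(level, Level):
        raise ValueError(f"unknown level {level!r}")
    a = sum(1 for m in index.members if term in _case_terms(m, level, meddra))
    c = sum(1 for m in reference.members if term in _case_terms(m, level, meddra))
    return ContingencyTable(a=a, b=len(index) - a, c=c, d=len(reference) - c)


def ror_woolf(
    t: ContingencyTable, z: float = Z_95
) -> tuple[float | None, float | None, float | None]:
    """Crude ROR with Woolf CI; (None, None, None) when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None, None, None
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def classify(ci_low: float | None, ci_high: float | None) -> Significance:
    if ci_low is None or ci_high is None:
        return Significance.NOT_ESTIMABLE
    if ci_low > 1.0:
        return Significance.POSITIVE
    if ci_high < 1.0:
        return Significance.NEGATIVE
    return Significance.NONE


def screen(
    index: Cohort,
    reference_full: Cohort,
    reference_norm: Cohort,
    level: Level,
    meddra: MeddraMap | None = None,
    expected: ExpectedTerms | None = None,
    min_cases: int = 3,
    z: float = Z_95,
) -> ScreenResult:
    """Screen every index-cohort term against both reference comparisons.

    Terms reported in fewer than ``min_cases`` index reports are not
    screened.  Terms absent from the index cohort but present in the full
    reference are listed separately (no ROR is computed for them).  Rows
    are sorted by decreasing normalized-comparison ROR (non-estimable
    last), ties by term.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    if not (reference_norm.case_ids <= reference_full.case_ids):
        raise ValueError("normalized reference must be a subset of the full reference")
    index_counts = _count_cases(index, level, meddra)
    full_counts = _count_cases(reference_full, level, meddra)
    norm_counts = _count_cases(reference_norm, level, meddra)

    per_term: list[tuple[str, SignalRow, SignalRow]] = []
    for term in sorted(t for t, a in index_counts.items() if a >= min_cases):
        a = index_counts[term]
        rows = {}
        for comparison, ref, counts in (
            ("full", reference_full, full_counts),
            ("normalized", reference_norm, norm_counts),
        ):
            c = counts.get(term, 0)
            tab = ContingencyTable(a=a, b=len(index) - a, c=c, d=len(ref) - c)
            ror, lo, hi = ror_woolf(tab, z=z)
            rows[comparison] = SignalRow(
                term=term, level=level, comparison=comparison, table=tab,
                ror=ror, ci_low=lo, ci_high=hi, significance=classify(lo, hi),
            )
        robust = all(
            rows[c].significance is Significance.POSITIVE
            for c in ("full", "normalized")
        )
        rows = {c: replace(r, robust=robust) for c, r in rows.items()}
        per_term.append((term, rows["full"], rows["normalized"]))

    def sort_key(item):
        _, _, norm_row = item
        ror = norm_row.ror
        return (-(ror if ror is not None else -math.inf), item[0])

    per_term.sort(key=sort_key)
    ordered: list[SignalRow] = []
    for _, full_row, norm_row in per_term:
        ordered.extend((norm_row, full_row))

    if expected is not None:
        ordered = list(annotate_expectedness(ordered, expected))

    reference_only = tuple(
        (t, c)
        for t, c in sorted(full_counts.items())
        if index_counts.get(t, 0) == 0 and c > 0
    )
    return ScreenResult(rows=tuple(ordered), reference_only=reference_only)


def annotate_expectedness(
    rows: Iterable[SignalRow], expected: ExpectedTerms
) -> list[SignalRow]:
    """Flag PT-level rows whose term appears in the expected-terms list.

    SOC-level rows get ``expected=None`` (expectedness is defined on PTs,
    the label's own granularity).
    """
    out = []
    for r in rows:
        if r.level is Level.PT:
            out.append(replace(r, expected=(r.term in expected)))
        else:
            out.append(replace(r, expected=None))
    return out
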