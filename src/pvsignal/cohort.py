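"""Cohort construction: exclusions, group assignment, windows and semesters.

The analysis compares an index drug's reports against a reference drug
class observed over a longer market period.  To blunt reporting-era bias
(the Weber effect), the reference cohort can be re-restricted to the same
post-launch duration as the index drug ("time-based normalization").
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from datetime import date

from .model import ICSR, norm_drug

logger = logging.getLogger(__name__)

__all__ = [
    "add_months",
    "GroupDefinition",
    "Cohort",
    "ExclusionRecord",
    "apply_exclusions",
    "build_cohort",
    "normalize_window",
    "semester_index",
]


def add_months(d: date, n: int) -> date:
    """Calendar month arithmetic with day-of-month clamping."""
    month_index = d.year * 12 + (d.month - 1) + n
    year, month = divmod(month_index, 12)
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


@dataclass(frozen=True)
class GroupDefinition:
    """One analysis group: drug set, launch date and observation window."""

    name: str
    suspect_drugs: frozenset[str]
    launch_date: date
    window_start: date
    window_end: date

    def __post_init__(self):
        object.__setattr__(
            self, "suspect_drugs", frozenset(norm_drug(d) for d in self.suspect_drugs)
        )
        if not self.suspect_drugs:
            raise ValueError(f"group {self.name!r}: suspect_drugs must be nonempty")
        if self.window_start > self.window_end:
            raise ValueError(f"group {self.name!r}: window_start after window_end")
        if self.window_start < self.launch_date:
            raise ValueError(f"group {self.name!r}: window starts before launch")


@dataclass(frozen=True)
class ExclusionRecord:
    case_id: str
    reasons: tuple[str, ...]


def apply_exclusions(collection: list[ICSR]) -> tuple[list[ICSR], list[ExclusionRecord]]:
    """Drop literature-linked and vaccine-suspect reports.

    Returns the kept reports (input order preserved) and one log record per
    excluded case listing every reason that applied.
    """
    kept: list[ICSR] = []
    log: list[ExclusionRecord] = []
    for icsr in collection:
        reasons = []
        if icsr.from_literature:
            reasons.append("literature")
        if icsr.has_vaccine_suspect:
            reasons.append("vaccine")
        if reasons:
            log.append(ExclusionRecord(icsr.case_id, tuple(reasons)))
        else:
            kept.append(icsr)
    return kept, log


@dataclass(frozen=True)
class Cohort:
    """Reports assigned to one analysis group.

    ``subgroup_labels[i]`` names which of the group's drugs member ``i``
    lists as suspect: the drug name when exactly one matches, ``"both"``
    when two do, otherwise the sorted ``"+"``-join.
    """

    name: str
    definition: GroupDefinition
    members: tuple[ICSR, ...]
    subgroup_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) != len(self.subgroup_labels):
            raise ValueError("members and subgroup_labels must align")
        ids = [m.case_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cohort {self.name!r}: duplicate case_id among members")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def case_ids(self) -> frozenset[str]:
        return frozenset(m.case_id for m in self.members)

    def subgroup_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.subgroup_labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def _subgroup_label(qualifying: frozenset[str]) -> str:
    if len(qualifying) == 1:
        return next(iter(qualifying))
    if len(qualifying) == 2:
        return "both"
    return "+".join(sorted(qualifying))


def build_cohort(collection: list[ICSR], definition: GroupDefinition) -> Cohort:
    """Assign reports to a group: >=1 qualifying suspect drug, date in window.

    A report joins the cohort once however many of the group's drugs it
    lists; the subgroup label records which drugs qualified.
    """
    members: list[ICSR] = []
    labels: list[str] = []
    for icsr in collection:
        qualifying = icsr.suspect_drugs & definition.suspect_drugs
        if not qualifying:
            continue
        if not (definition.window_start <= icsr.report_date <= definition.window_end):
            continue
        members.append(icsr)
        labels.append(_subgroup_label(qualifying))
    return Cohort(definition.name, definition, tuple(members), tuple(labels))


def normalize_window(cohort: Cohort, months: int = 30) -> Cohort:
    """Restrict a cohort to its first ``months`` months post launch.

    Keeps members dated in ``[launch, launch + months)`` with calendar-month
    arithmetic; idempotent, and always a subset of the input.
    """
    if months <= 0:
        raise ValueError("months must be positive")
    launch = cohort.definition.launch_date
    cutoff = add_months(launch, months)  # exclusive
    pairs = [
        (m, lab)
        for m, lab in zip(cohort.members, cohort.subgroup_labels)
        if launch <= m.report_date < cutoff
    ]
    members = tuple(p[0] for p in pairs)
    labels = tuple(p[1] for p in pairs)
    return Cohort(cohort.name, cohort.definition, members, labels)


def semester_index(report_date: date, launch_date: date) -> int:
    """1-based post-launch semester containing ``report_date``.

    Semester k covers ``[launch + 6(k-1) months, launch + 6k months)``.
    """
    if report_date < launch_date:
        raise ValueError(
            f"report date {report_date} precedes launch {launch_date}")
    k = 1
    while add_months(launch_date, 6 * k) <= report_date:
        k += 1
    return k


def overlap_warning(cohorts: list[Cohort]) -> list[str]:
    """Case ids present in more than one cohort (logged as a warning)."""
    seen: dict[str, int] = {}
    for c in cohorts:
        for cid in c.case_ids:
            seen[cid] = seen.get(cid, 0) + 1
    dupes = sorted(cid for cid, n in seen.items() if n > 1)
    if dupes:
        logger.warning("%d case(s) belong to more than one cohort: %s",
                       len(dupes), ", ".join(dupes[:10]))
    return dupes
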