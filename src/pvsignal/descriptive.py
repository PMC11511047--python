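"""Descriptive comparison of two report cohorts.

Reproduces the usual pharmacovigilance characteristics table: absolute
frequencies and percentages per category, with per-category two-tailed
Pearson chi-square comparisons between cohorts, plus semester reporting
trends, per-SOC report frequencies and reactions-per-report summaries.

Denominator conventions
-----------------------
Sex, dichotomized age and the case-level global outcome are reported as
percentages among *known* values (the Unknown row keeps the whole cohort as
its denominator); seriousness, reporter qualification and region are
percentages of the whole cohort.  Chi-square tests use known categories
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, semester_index
from .model import AgeGroup, ICSR, MeddraMap, Outcome, Region, Sex, SourceQualification
from .rounding import pct, round_half_up

__all__ = [
    "AgeDichotomy",
    "resolve_global_outcome",
    "dichotomize_age",
    "pearson_chi2",
    "CharacteristicsTable",
    "characteristics_table",
    "semester_trend",
    "soc_frequencies",
    "reactions_per_icsr",
]

# Worst-outcome-dominates severity order ("lower level of resolution"):
# a case's global outcome is the most severe outcome among its reactions,
# with Unknown weakest (Unknown only if every outcome is Unknown).
_SEVERITY = {
    Outcome.FATAL: 5,
    Outcome.NOT_RECOVERED: 4,
    Outcome.RECOVERED_WITH_SEQUELAE: 3,
    Outcome.RECOVERING_RESOLVING: 2,
    Outcome.RECOVERED_RESOLVED: 1,
    Outcome.UNKNOWN: 0,
}


class AgeDichotomy(Enum):
    UNDER_65 = "<65"
    OVER_EQ_65 = ">=65"
    UNKNOWN = "Unknown"


def resolve_global_outcome(outcomes: Sequence[Outcome]) -> Outcome:
    """Case-level outcome: the most severe of the per-reaction outcomes."""
    if not outcomes:
        raise ValueError("cannot resolve a global outcome from no outcomes")
    return max(outcomes, key=_SEVERITY.__getitem__)


def dichotomize_age(age_group: AgeGroup) -> AgeDichotomy:
    if age_group is AgeGroup.NOT_SPECIFIED:
        return AgeDichotomy.UNKNOWN
    if age_group in (AgeGroup.Y65_85, AgeGroup.Y85_PLUS):
        return AgeDichotomy.OVER_EQ_65
    return AgeDichotomy.UNDER_65


def pearson_chi2(table, row_labels: Sequence[str] | None = None,
                 col_labels: Sequence[str] | None = None) -> tuple[float, int, float]:
    """Two-tailed Pearson chi-square on an r x c count table.

    No continuity correction; expected counts from the product of margins.
    A zero row or column margin is an error naming the offending category.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("chi-square table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("chi-square table contains negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    for i, s in enumerate(rows):
        if s == 0:
            name = row_labels[i] if row_labels else f"row {i}"
            raise ValueError(f"zero margin for category {name!r}")
    for j, s in enumerate(cols):
        if s == 0:
            name = col_labels[j] if col_labels else f"column {j}"
            raise ValueError(f"zero margin for category {name!r}")
    total = obs.sum()
    expected = np.outer(rows, cols) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


# variable name -> (extractor, known-only percentages?, category order, unknown category)
def _case_sex(m: ICSR) -> str:
    return m.sex.label


def _case_age(m: ICSR) -> str:
    return {"<65": "<65", ">=65": ">=65", "Unknown": "Unknown"}[
        dichotomize_age(m.age_group).value]


def _case_serious(m: ICSR) -> str:
    return "Serious" if m.serious else "Non-serious"


def _case_outcome(m: ICSR) -> str:
    return resolve_global_outcome([r.outcome for r in m.reactions]).label


def _case_source(m: ICSR) -> str:
    return m.source_qualification.label


def _case_region(m: ICSR) -> str:
    return m.region.short_label


_VARIABLES: dict[str, tuple] = {
    "sex": (_case_sex, True, [Sex.MALE.label, Sex.FEMALE.label], Sex.UNKNOWN.label),
    "age_dichotomy": (_case_age, True, ["<65", ">=65"], "Unknown"),
    "seriousness": (_case_serious, False, ["Serious", "Non-serious"], None),
    "global_outcome": (
        _case_outcome,
        True,
        [
            Outcome.FATAL.label,
            Outcome.NOT_RECOVERED.label,
            Outcome.RECOVERED_WITH_SEQUELAE.label,
            Outcome.RECOVERING_RESOLVING.label,
            Outcome.RECOVERED_RESOLVED.label,
        ],
        Outcome.UNKNOWN.label,
    ),
    "source_qualification": (
        _case_source, False,
        [SourceQualification.HEALTHCARE_PROFESSIONAL.label,
         SourceQualification.NON_HEALTHCARE_PROFESSIONAL.label],
        None,
    ),
    "region": (_case_region, False, ["EEA", "Non-EEA"], None),
}


@dataclass
class CharacteristicsTable:
    """Long-format characteristics table plus per-variable omnibus tests.

    ``rows`` columns: variable, category, cohort, count, denominator, pct,
    p_value (per-category 2x2 test across cohorts; NaN for Unknown rows and
    untestable variables).  ``variable_tests`` maps variable ->
    (statistic, df, p) for the omnibus chi-square over known categories.
    """

    rows: pd.DataFrame
    variable_tests: dict[str, tuple[float, int, float]]

    def lookup(self, variable: str, category: str, cohort: str) -> pd.Series:
        sel = self.rows[
            (self.rows.variable == variable)
            & (self.rows.category == category)
            & (self.rows.cohort == cohort)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique row for {variable}/{category}/{cohort}")
        return sel.iloc[0]

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def characteristics_table(cohort_a: Cohort, cohort_b: Cohort) -> CharacteristicsTable:
    """Compare two cohorts across the six standard report characteristics."""
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValueError("characteristics_table requires nonempty cohorts")
    cohorts = [cohort_a, cohort_b]
    records = []
    variable_tests: dict[str, tuple[float, int, float]] = {}
    for var, (extract, known_only, categories, unknown_cat) in _VARIABLES.items():
        counts = []  # per cohort: {category: n}
        for c in cohorts:
            vals = [extract(m) for m in c.members]
            counts.append({cat: vals.count(cat) for cat in categories}
                          | ({unknown_cat: vals.count(unknown_cat)} if unknown_cat else {}))
        known_totals = [sum(ct[cat] for cat in categories) for ct in counts]
        # omnibus chi-square over known categories (skip all-zero categories)
        used = [cat for cat in categories if any(ct[cat] for ct in counts)]
        try:
            obs = [[ct[cat] for ct in counts] for cat in used]
            variable_tests[var] = pearson_chi2(obs, row_labels=used,
                                               col_labels=[c.name for c in cohorts])
        except ValueError:
            variable_tests[var] = (float("nan"), 0, float("nan"))
        for cat in categories + ([unknown_cat] if unknown_cat else []):
            is_unknown = unknown_cat is not None and cat == unknown_cat
            # per-category 2x2: category vs rest of the known categories
            if is_unknown or cat not in used or len(used) < 2:
                p_cat = float("nan")
            else:
                t = [[counts[i][cat], known_totals[i] - counts[i][cat]]
                     for i in range(2)]
                try:
                    _, _, p_cat = pearson_chi2(t, row_labels=[cat, "other"],
                                               col_labels=[c.name for c in cohorts])
                except ValueError:
                    p_cat = float("nan")
            for i, c in enumerate(cohorts):
                n = counts[i][cat]
                denom = len(c) if (is_unknown or not known_only) else known_totals[i]
                records.append({
                    "variable": var,
                    "category": cat,
                    "cohort": c.name,
                    "count": n,
                    "denominator": denom,
                    "pct": pct(n, denom) if denom > 0 else float("nan"),
                    "p_value": p_cat,
                })
    return CharacteristicsTable(pd.DataFrame.from_records(records), variable_tests)


def semester_trend(cohort: Cohort, launch_date: date, n_semesters: int) -> pd.DataFrame:
    """Report counts per post-launch semester, split by subgroup label.

    Rows are semesters 1..n_semesters; columns are the cohort's subgroup
    labels plus ``total``.  Reports beyond semester ``n_semesters`` are not
    tabulated.
    """
    labels = sorted(set(cohort.subgroup_labels))
    data = {lab: [0] * n_semesters for lab in labels}
    total = [0] * n_semesters
    for m, lab in zip(cohort.members, cohort.subgroup_labels):
        k = semester_index(m.report_date, launch_date)
        if 1 <= k <= n_semesters:
            data[lab][k - 1] += 1
            total[k - 1] += 1
    df = pd.DataFrame(data, index=pd.RangeIndex(1, n_semesters + 1, name="semester"))
    df["total"] = total
    return df


def soc_frequencies(cohort: Cohort, meddra: MeddraMap) -> pd.DataFrame:
    """Per-SOC report counts: a report counts once per SOC it touches.

    Percentages use the cohort size as denominator, so the column does not
    sum to 100 (one report can span several SOCs).
    """
    n = len(cohort)
    counts: dict[str, int] = {}
    for m in cohort.members:
        socs = {meddra.soc_of(p) for p in m.pts}
        for s in socs:
            counts[s] = counts.get(s, 0) + 1
    rows = [
        {"soc": s, "n_icsrs": c, "pct": pct(c, n) if n else float("nan")}
        for s, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["soc", "n_icsrs", "pct"])
    return df.sort_values(["n_icsrs", "soc"], ascending=[False, True],
                          ignore_index=True)


def reactions_per_icsr(cohort_or_members) -> dict[str, float]:
    """Total suspected reactions and mean per report (half-up, 1 decimal)."""
    members: Iterable[ICSR] = (
        cohort_or_members.members
        if isinstance(cohort_or_members, Cohort)
        else list(cohort_or_members)
    )
    members = list(members)
    if not members:
        raise ValueError("reactions_per_icsr requires a nonempty cohort")
    total = sum(len(m.reactions) for m in members)
    return {
        "n_icsrs": len(members),
        "total_reactions": total,
        "mean_per_icsr": round_half_up(total / len(members), 1),
    }
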