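"""Worked-example cohorts reconstructed from published marginal counts.

Public surveillance summaries print only marginal frequencies (so many
serious cases, so many fatal outcomes, so many reports per drug...), not
the underlying line listing.  This module rebuilds synthetic cohorts whose
margins equal those printed for the inclisiran vs PCSK9-antibody
comparison, so the descriptive and disproportionality stages can be
exercised end to end against the published numbers: 563 index reports and
14,673 reference reports (9,562 evolocumab / 5,016 alirocumab / 95 dual
suspect), 1,717 of which fall in the first 30 post-launch months.

Variables are assigned independently by report position, which preserves
every univariate margin (the only quantities the checks read back) without
claiming anything about the real joint distribution.  The reconstruction is
fully deterministic and uses no randomness.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Sequence

from .cohort import Cohort, GroupDefinition, build_cohort
from .model import (
    AgeGroup,
    ICSR,
    Outcome,
    Reaction,
    Region,
    SeriousnessCriterion,
    Sex,
    SourceQualification,
)

__all__ = [
    "INDEX_MARGINS",
    "worked_index_cohort",
    "worked_reference_cohort",
]

# Printed margins of the index (inclisiran) cohort.
INDEX_MARGINS = {
    "n": 563,
    "sex": [(Sex.MALE, 264), (Sex.FEMALE, 283), (Sex.UNKNOWN, 16)],
    "age": [(AgeGroup.Y18_64, 112), (AgeGroup.Y65_85, 100),
            (AgeGroup.NOT_SPECIFIED, 351)],
    "serious": 141,
    "outcome": [(Outcome.FATAL, 4), (Outcome.NOT_RECOVERED, 123),
                (Outcome.RECOVERED_WITH_SEQUELAE, 5),
                (Outcome.RECOVERING_RESOLVING, 55),
                (Outcome.RECOVERED_RESOLVED, 116), (Outcome.UNKNOWN, 260)],
    "hcp": 486,
    "eea": 495,
    "total_reactions": 1468,
    "myalgia_cases": 99,
}

# Reference cohort margins: full and first-30-months (normalized) block.
_REF_N = 14673
_REF_NORM = {"evolocumab": 991, "alirocumab": 712, "both": 14}  # 1717
_REF_FULL = {"evolocumab": 9562, "alirocumab": 5016, "both": 95}
_REF_TOTAL_REACTIONS = 36212
_REF_MYALGIA = 1174          # round(0.080 * 14673), full cohort
_REF_MYALGIA_NORM = 141      # round(0.082 * 1717), normalized block
_REF_NORM_OUTCOME = [
    (Outcome.FATAL, 62), (Outcome.NOT_RECOVERED, 320),
    (Outcome.RECOVERED_WITH_SEQUELAE, 2), (Outcome.RECOVERING_RESOLVING, 135),
    (Outcome.RECOVERED_RESOLVED, 403), (Outcome.UNKNOWN, 795),
]
_REF_NORM_SERIOUS = 1406
_REF_FULL_SERIOUS = 8634


def _spread(counts: Sequence[tuple], total: int, fill):
    """Expand (value, n) pairs to a list of length ``total``, padding with
    ``fill``."""
    out = []
    for value, n in counts:
        out.extend([value] * n)
    if len(out) > total:
        raise ValueError("margins exceed cohort size")
    out.extend([fill] * (total - len(out)))
    return out


def _make_reactions(i: int, n_three: int, outcome: Outcome, serious: bool,
                    special_pt: str | None) -> tuple[Reaction, ...]:
    n_reactions = 3 if i < n_three else 2
    if outcome is Outcome.FATAL:
        criteria = frozenset({SeriousnessCriterion.DEATH})
    elif serious:
        criteria = frozenset({SeriousnessCriterion.OTHER_MEDICALLY_IMPORTANT})
    else:
        criteria = frozenset()
    pts = [special_pt] if special_pt else ["Background event"]
    while len(pts) < n_reactions:
        pts.append("Background event")
    # all reactions share the case outcome so the global outcome resolves
    # to exactly the assigned category; criteria sit on the first reaction
    return tuple(
        Reaction(pt=pt, outcome=outcome,
                 seriousness_criteria=criteria if j == 0 else frozenset())
        for j, pt in enumerate(pts)
    )


def worked_index_cohort() -> Cohort:
    """The 563-report index cohort with every printed margin reproduced."""
    n = INDEX_MARGINS["n"]
    sex = _spread(INDEX_MARGINS["sex"], n, Sex.UNKNOWN)
    age = _spread(INDEX_MARGINS["age"], n, AgeGroup.NOT_SPECIFIED)
    outcome = _spread(INDEX_MARGINS["outcome"], n, Outcome.UNKNOWN)
    serious = [i < INDEX_MARGINS["serious"] for i in range(n)]
    hcp = [i < INDEX_MARGINS["hcp"] for i in range(n)]
    eea = [i < INDEX_MARGINS["eea"] for i in range(n)]
    myalgia = [i < INDEX_MARGINS["myalgia_cases"] for i in range(n)]
    n_three = INDEX_MARGINS["total_reactions"] - 2 * n  # reports with 3 reactions

    launch = date(2021, 1, 1)
    members = [
        ICSR(
            case_id=f"I-{i:05d}",
            report_date=launch + timedelta(days=i % 900),
            source_qualification=(
                SourceQualification.HEALTHCARE_PROFESSIONAL if hcp[i]
                else SourceQualification.NON_HEALTHCARE_PROFESSIONAL),
            sex=sex[i],
            age_group=age[i],
            region=Region.EEA if eea[i] else Region.NON_EEA,
            suspect_drugs=frozenset({"inclisiran"}),
            reactions=_make_reactions(i, n_three, outcome[i], serious[i],
                                      "Myalgia" if myalgia[i] else None),
        )
        for i in range(n)
    ]
    definition = GroupDefinition(
        name="inclisiran", suspect_drugs=frozenset({"inclisiran"}),
        launch_date=launch, window_start=launch, window_end=date(2023, 6, 30))
    return build_cohort(members, definition)


def worked_reference_cohort() -> Cohort:
    """The 14,673-report reference cohort.

    The first 1,717 members are dated inside the first 30 post-launch
    months (the normalized block) and carry that block's printed outcome,
    seriousness and subgroup margins; the remainder are dated later.
    """
    launch = date(2015, 1, 1)
    n_norm = sum(_REF_NORM.values())
    norm_drugs = _spread(
        [(("evolocumab",), _REF_NORM["evolocumab"]),
         (("alirocumab",), _REF_NORM["alirocumab"]),
         (("evolocumab", "alirocumab"), _REF_NORM["both"])],
        n_norm, ("evolocumab",))
    rest = {k: _REF_FULL[k] - _REF_NORM[k] for k in _REF_FULL}
    n_rest = sum(rest.values())
    rest_drugs = _spread(
        [(("evolocumab",), rest["evolocumab"]),
         (("alirocumab",), rest["alirocumab"]),
         (("evolocumab", "alirocumab"), rest["both"])],
        n_rest, ("evolocumab",))
    drugs = norm_drugs + rest_drugs

    outcome = (_spread(_REF_NORM_OUTCOME, n_norm, Outcome.UNKNOWN)
               + [Outcome.UNKNOWN] * n_rest)
    serious = ([i < _REF_NORM_SERIOUS for i in range(n_norm)]
               + [i < _REF_FULL_SERIOUS - _REF_NORM_SERIOUS for i in range(n_rest)])
    myalgia = ([i < _REF_MYALGIA_NORM for i in range(n_norm)]
               + [i < _REF_MYALGIA - _REF_MYALGIA_NORM for i in range(n_rest)])
    n_three = _REF_TOTAL_REACTIONS - 2 * _REF_N

    # fatal cases in the normalized block must remain serious: they are,
    # by construction (DEATH criterion attached in _make_reactions)
    members = []
    for i in range(_REF_N):
        if i < n_norm:
            report_date = launch + timedelta(days=i % 900)
        else:
            report_date = date(2017, 7, 1) + timedelta(days=i % 2100)
        members.append(ICSR(
            case_id=f"R-{i:05d}",
            report_date=report_date,
            source_qualification=SourceQualification.HEALTHCARE_PROFESSIONAL,
            sex=Sex.UNKNOWN,
            age_group=AgeGroup.NOT_SPECIFIED,
            region=Region.NON_EEA,
            suspect_drugs=frozenset(drugs[i]),
            reactions=_make_reactions(i, n_three, outcome[i], serious[i],
                                      "Myalgia" if myalgia[i] else None),
        ))
    definition = GroupDefinition(
        name="pcsk9a", suspect_drugs=frozenset({"evolocumab", "alirocumab"}),
        launch_date=launch, window_start=launch, window_end=date(2023, 6, 30))
    return build_cohort(members, definition)
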