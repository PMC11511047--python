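"""ROR engine: closed forms, algebraic properties, screening rules."""

from __future__ import annotations

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.cohort import Cohort, GroupDefinition, build_cohort
from pvsignal.disproportionality import (
    ContingencyTable,
    Level,
    Significance,
    annotate_expectedness,
    classify,
    ror_woolf,
    screen,
    term_contingency,
)
from pvsignal.model import (
    AgeGroup,
    ExpectedTerms,
    ICSR,
    MeddraMap,
    Outcome,
    Reaction,
    Region,
    Sex,
    SourceQualification,
)

MAP = MeddraMap({
    "Myalgia": "Musculoskeletal and connective tissue disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Nausea": "Gastrointestinal disorders",
})


def make_icsr(case_id, pts, drug):
    return ICSR(
        case_id=case_id,
        report_date=date(2021, 6, 1),
        source_qualification=SourceQualification.HEALTHCARE_PROFESSIONAL,
        sex=Sex.FEMALE, age_group=AgeGroup.Y18_64, region=Region.EEA,
        suspect_drugs=frozenset({drug}),
        reactions=tuple(Reaction(pt, Outcome.UNKNOWN) for pt in pts),
    )


def make_cohort(members, name, drug, launch=date(2021, 1, 1)):
    definition = GroupDefinition(
        name=name, suspect_drugs=frozenset({drug}), launch_date=launch,
        window_start=launch, window_end=date(2023, 12, 31))
    return build_cohort(members, definition)


def test_ror_balanced_table():
    ror, lo, hi = ror_woolf(ContingencyTable(10, 10, 10, 10))
    assert ror == 1.0
    assert lo == pytest.approx(math.exp(-1.959964 * math.sqrt(0.4)), rel=1e-9)
    assert hi == pytest.approx(math.exp(+1.959964 * math.sqrt(0.4)), rel=1e-9)
    assert (round(lo, 2), round(hi, 2)) == (0.29, 3.45)


def test_ror_integer_arithmetic_oracle():
    ror, _, _ = ror_woolf(ContingencyTable(5, 95, 5, 195))
    assert ror == pytest.approx(975 / 475, rel=1e-12)


def test_zero_cell_not_estimable_and_negative_rejected():
    assert ror_woolf(ContingencyTable(0, 10, 5, 5)) == (None, None, None)
    assert ror_woolf(ContingencyTable(3, 10, 0, 5)) == (None, None, None)
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)
    assert classify(None, None) is Significance.NOT_ESTIMABLE


_cells = st.integers(1, 2000)


@settings(max_examples=300, derandomize=True)
@given(_cells, _cells, _cells, _cells)
def test_ci_geometric_mean_identity_and_antisymmetry(a, b, c, d):
    """sqrt(lo*hi) = ROR; swapping cohorts reciprocates ROR and swaps CI."""
    ror, lo, hi = ror_woolf(ContingencyTable(a, b, c, d))
    assert math.sqrt(lo * hi) == pytest.approx(ror, rel=1e-9)
    ror2, lo2, hi2 = ror_woolf(ContingencyTable(c, d, a, b))
    assert ror2 == pytest.approx(1 / ror, rel=1e-9)
    assert lo2 == pytest.approx(1 / hi, rel=1e-9)
    assert hi2 == pytest.approx(1 / lo, rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(_cells, _cells, _cells, _cells)
def test_ror_monotone_in_a(a, b, c, d):
    r1, _, _ = ror_woolf(ContingencyTable(a, b, c, d))
    r2, _, _ = ror_woolf(ContingencyTable(a + 1, b, c, d))
    assert r2 > r1


def test_term_contingency_counts_cases_once():
    index = make_cohort(
        [make_icsr("I-1", ["Myalgia", "Myalgia "], "inclisiran"),  # dup PT
         make_icsr("I-2", ["Nausea"], "inclisiran"),
         make_icsr("I-3", ["Myalgia", "Arthralgia"], "inclisiran")],
        "inclisiran", "inclisiran")
    reference = make_cohort(
        [make_icsr("R-1", ["Myalgia"], "evolocumab"),
         make_icsr("R-2", ["Nausea"], "evolocumab")],
        "pcsk9a", "evolocumab")
    t = term_contingency(index, reference, "Myalgia", Level.PT)
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)
    # SOC level: I-3's two musculoskeletal PTs still count once
    t2 = term_contingency(index, reference,
                          "Musculoskeletal and connective tissue disorders",
                          Level.SOC, MAP)
    assert (t2.a, t2.c) == (2, 1)


def test_term_contingency_agrees_with_brute_force(fifty_reports):
    """Independent brute-force scan over raw reports on small cohorts."""
    collection, meddra, _ = fifty_reports
    index = make_cohort([m for m in collection if "druga" in m.suspect_drugs],
                        "a", "druga")
    reference = make_cohort([m for m in collection if "drugb" in m.suspect_drugs],
                            "b", "drugb", launch=date(2020, 1, 1))
    pts = sorted({r.pt for m in collection for r in m.reactions})
    for pt in pts:
        t = term_contingency(index, reference, pt, Level.PT)
        a_bf = len({m.case_id for m in index.members
                    for r in m.reactions if r.pt == pt})
        c_bf = len({m.case_id for m in reference.members
                    for r in m.reactions if r.pt == pt})
        assert (t.a, t.c) == (a_bf, c_bf)
        assert t.a + t.b == len(index)
        assert t.c + t.d == len(reference)


def _screen_cohorts():
    index_members = (
        [make_icsr(f"I-{i}", ["Myalgia"], "inclisiran") for i in range(5)]
        + [make_icsr("I-R1", ["Arthralgia"], "inclisiran")]  # a=1 < min_cases
        + [make_icsr(f"I-N{i}", ["Nausea"], "inclisiran") for i in range(3)]
    )
    ref_members = (
        [make_icsr(f"R-{i}", ["Myalgia"], "evolocumab") for i in range(2)]
        + [make_icsr(f"R-N{i}", ["Nausea"], "evolocumab") for i in range(6)]
        + [make_icsr("R-MI", ["Myocardial infarction"], "evolocumab")]
        + [make_icsr(f"R-X{i}", ["Pruritus"], "evolocumab") for i in range(10)]
    )
    index = make_cohort(index_members, "inclisiran", "inclisiran")
    reference = make_cohort(ref_members, "pcsk9a", "evolocumab")
    return index, reference


def test_screen_min_cases_reference_only_and_ordering():
    index, reference = _screen_cohorts()
    res = screen(index, reference, reference, Level.PT,
                 expected=ExpectedTerms(["Myalgia"]), min_cases=3)
    terms = {r.term for r in res.rows}
    assert terms == {"Myalgia", "Nausea"}      # Arthralgia filtered (a=1)
    assert ("Myocardial infarction", 1) in res.reference_only
    assert ("Pruritus", 10) in res.reference_only
    assert all(t not in terms for t, _ in res.reference_only)
    # each screened term appears once per comparison
    for term in terms:
        comps = [r.comparison for r in res.rows if r.term == term]
        assert sorted(comps) == ["full", "normalized"]
    # sorted by decreasing normalized ROR
    norm_rors = [r.ror for r in res.rows if r.comparison == "normalized"]
    assert norm_rors == sorted(norm_rors, key=lambda x: -x)
    # expectedness annotation
    myalgia = next(r for r in res.rows if r.term == "Myalgia")
    nausea = next(r for r in res.rows if r.term == "Nausea")
    assert myalgia.expected is True
    assert nausea.expected is False
    with pytest.raises(ValueError):
        screen(index, reference, reference, Level.PT, min_cases=0)


def test_screen_robust_requires_both_comparisons_positive():
    index, reference = _screen_cohorts()
    # normalized reference = only the non-myalgia reports: myalgia c=0 there
    norm = Cohort(reference.name, reference.definition,
                  reference.members[2:], reference.subgroup_labels[2:])
    res = screen(index, reference, norm, Level.PT, min_cases=3)
    myalgia_rows = [r for r in res.rows if r.term == "Myalgia"]
    assert {r.comparison: r.significance for r in myalgia_rows}[
        "normalized"] is Significance.NOT_ESTIMABLE
    assert not any(r.robust for r in myalgia_rows)


def test_screen_rejects_non_subset_normalized_reference():
    index, reference = _screen_cohorts()
    with pytest.raises(ValueError):
        screen(index, reference, index, Level.PT)


def test_soc_rows_have_no_expectedness():
    index, reference = _screen_cohorts()
    res = screen(index, reference, reference, Level.SOC, meddra=MAP,
                 expected=ExpectedTerms(["Myalgia"]), min_cases=3)
    assert res.rows
    assert all(r.expected is None for r in res.rows)


def test_annotate_expectedness_empty_set_all_false():
    index, reference = _screen_cohorts()
    res = screen(index, reference, reference, Level.PT, min_cases=3)
    rows = annotate_expectedness(res.rows, ExpectedTerms([]))
    assert all(r.expected is False for r in rows)


def test_null_term_rarely_flags_positive():
    """A true-OR-1 term flags positive in well under 7% of replicates."""
    rng = np.random.default_rng(99)
    n, p, reps = 2000, 0.05, 400
    fired = 0
    for _ in range(reps):
        a = rng.binomial(n, p)
        c = rng.binomial(n, p)
        _, lo, _ = ror_woolf(ContingencyTable(a, n - a, c, n - c))
        if lo is not None and lo > 1:
            fired += 1
    assert fired / reps <= 0.07
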