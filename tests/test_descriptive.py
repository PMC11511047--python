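"""Descriptive stage: global outcome, chi-square, tables, SOC counts."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pvsignal.cohort import Cohort, GroupDefinition, build_cohort
from pvsignal.descriptive import (
    AgeDichotomy,
    characteristics_table,
    dichotomize_age,
    pearson_chi2,
    reactions_per_icsr,
    resolve_global_outcome,
    semester_trend,
    soc_frequencies,
)
from pvsignal.model import (
    AgeGroup,
    ICSR,
    MeddraMap,
    Outcome,
    Reaction,
    Region,
    Sex,
    SourceQualification,
)
from pvsignal.rounding import round_half_up


def make_icsr(case_id, pts, report_date=date(2021, 6, 1), drug="inclisiran"):
    return ICSR(
        case_id=case_id,
        report_date=report_date,
        source_qualification=SourceQualification.HEALTHCARE_PROFESSIONAL,
        sex=Sex.FEMALE,
        age_group=AgeGroup.Y18_64,
        region=Region.EEA,
        suspect_drugs=frozenset({drug}),
        reactions=tuple(Reaction(pt, Outcome.UNKNOWN) for pt in pts),
    )


def make_cohort(members, name="inclisiran", launch=date(2021, 1, 1)):
    definition = GroupDefinition(
        name=name, suspect_drugs=frozenset({"inclisiran"}),
        launch_date=launch, window_start=launch, window_end=date(2023, 6, 30))
    return build_cohort(members, definition)


# --- global outcome ---------------------------------------------------------

@pytest.mark.parametrize("outcomes,expected", [
    ([Outcome.UNKNOWN, Outcome.UNKNOWN], Outcome.UNKNOWN),
    ([Outcome.RECOVERED_RESOLVED, Outcome.FATAL], Outcome.FATAL),
    ([Outcome.RECOVERING_RESOLVING, Outcome.RECOVERED_WITH_SEQUELAE,
      Outcome.UNKNOWN], Outcome.RECOVERED_WITH_SEQUELAE),
    ([Outcome.RECOVERED_RESOLVED, Outcome.NOT_RECOVERED], Outcome.NOT_RECOVERED),
])
def test_global_outcome_worst_dominates(outcomes, expected):
    assert resolve_global_outcome(outcomes) is expected


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.sampled_from(list(Outcome)), min_size=1, max_size=6),
       st.randoms(use_true_random=False))
def test_global_outcome_order_and_duplication_invariant(outcomes, rnd):
    base = resolve_global_outcome(outcomes)
    shuffled = list(outcomes) + [outcomes[0]]
    rnd.shuffle(shuffled)
    assert resolve_global_outcome(shuffled) is base
    assert resolve_global_outcome([base]) is base  # idempotent on singletons


def test_global_outcome_empty_list_is_error():
    with pytest.raises(ValueError):
        resolve_global_outcome([])


# --- age dichotomy ----------------------------------------------------------

@pytest.mark.parametrize("age,expected", [
    (AgeGroup.M_0_1, AgeDichotomy.UNDER_65),
    (AgeGroup.Y3_11, AgeDichotomy.UNDER_65),
    (AgeGroup.Y18_64, AgeDichotomy.UNDER_65),
    (AgeGroup.Y65_85, AgeDichotomy.OVER_EQ_65),
    (AgeGroup.Y85_PLUS, AgeDichotomy.OVER_EQ_65),
    (AgeGroup.NOT_SPECIFIED, AgeDichotomy.UNKNOWN),
])
def test_dichotomize_age(age, expected):
    assert dichotomize_age(age) is expected


# --- Pearson chi-square -----------------------------------------------------

def test_chi2_closed_form_2x2():
    stat, df, p = pearson_chi2([[20, 30], [30, 20]])
    assert stat == pytest.approx(4.0, abs=1e-12)
    assert df == 1
    stat0, _, p0 = pearson_chi2([[10, 10], [10, 10]])
    assert stat0 == 0 and p0 == 1.0


def test_chi2_seriousness_worked_numbers():
    _, _, p = pearson_chi2([[141, 422], [1406, 311]])
    assert p < 0.001


def test_chi2_zero_margin_names_category():
    with pytest.raises(ValueError, match="Fatal"):
        pearson_chi2([[0, 0], [10, 20]], row_labels=["Fatal", "Other"])


@settings(max_examples=200, derandomize=True)
@given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500),
       st.integers(1, 500))
def test_chi2_matches_closed_form_and_scipy(a, b, c, d):
    """Statistic equals N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)) and scipy's value."""
    stat, df, p = pearson_chi2([[a, b], [c, d]])
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert stat == pytest.approx(closed, rel=1e-10)
    ref = chi2_contingency([[a, b], [c, d]], correction=False)
    assert stat == pytest.approx(ref.statistic, rel=1e-10)
    assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-300)


# --- characteristics table --------------------------------------------------

def test_identical_cohorts_give_p_of_one(fifty_reports):
    collection, _, _ = fifty_reports
    definition = GroupDefinition(
        name="a", suspect_drugs=frozenset({"druga"}),
        launch_date=date(2021, 1, 1), window_start=date(2021, 1, 1),
        window_end=date(2023, 6, 30))
    a = build_cohort(collection, definition)
    assert len(a) == 30
    b = Cohort("b", definition, a.members, a.subgroup_labels)
    table = characteristics_table(a, b)
    for var, (stat, df, p) in table.variable_tests.items():
        if not np.isnan(p):
            assert p == pytest.approx(1.0)
    ps = table.rows.p_value.dropna()
    assert (ps > 0.999).all()


def test_characteristics_counts_partition_cohort(fixture_sim):
    collection, _, _ = fixture_sim
    idx = make_cohort([m for m in collection if "inclisiran" in m.suspect_drugs])
    ref_def = GroupDefinition(
        name="pcsk9a", suspect_drugs=frozenset({"evolocumab", "alirocumab"}),
        launch_date=date(2015, 1, 1), window_start=date(2015, 1, 1),
        window_end=date(2023, 6, 30))
    ref = build_cohort(collection, ref_def)
    table = characteristics_table(idx, ref)
    # known counts + unknown count = cohort size for every variable
    for cohort in (idx, ref):
        for var in table.rows.variable.unique():
            sub = table.rows[(table.rows.variable == var)
                             & (table.rows.cohort == cohort.name)]
            assert sub["count"].sum() == len(cohort), var


# --- SOC frequencies --------------------------------------------------------

SOC_MAP = MeddraMap({
    "Myalgia": "Musculoskeletal and connective tissue disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Nausea": "Gastrointestinal disorders",
    "Headache": "Nervous system disorders",
})


def test_soc_counting_is_per_icsr():
    cohort = make_cohort([
        make_icsr("S-1", ["Myalgia", "Arthralgia"]),   # same SOC twice -> 1
        make_icsr("S-2", ["Nausea"]),
    ])
    df = soc_frequencies(cohort, SOC_MAP).set_index("soc")
    assert df.loc["Musculoskeletal and connective tissue disorders", "n_icsrs"] == 1
    assert df.loc["Gastrointestinal disorders", "n_icsrs"] == 1
    assert (df.pct <= 100).all()


def test_single_icsr_spanning_three_socs():
    cohort = make_cohort([make_icsr("S-1", ["Myalgia", "Nausea", "Headache"])])
    df = soc_frequencies(cohort, SOC_MAP)
    assert len(df) == 3
    assert (df.pct == 100.0).all()


def test_unmapped_pt_appears_as_sentinel_soc():
    cohort = make_cohort([make_icsr("S-1", ["Completely novel event"])])
    df = soc_frequencies(cohort, SOC_MAP)
    assert list(df.soc) == ["Unmapped"]


# --- reactions per report, trend --------------------------------------------

def test_reactions_per_icsr_mean_rounding():
    cohort = make_cohort([
        make_icsr("R-1", ["Myalgia"]),
        make_icsr("R-2", ["Myalgia", "Nausea"]),
    ])
    out = reactions_per_icsr(cohort)
    assert out == {"n_icsrs": 2, "total_reactions": 3, "mean_per_icsr": 1.5}
    with pytest.raises(ValueError):
        reactions_per_icsr([])
    assert round_half_up(2.45, 1) == 2.5  # half-up, not banker's


def test_semester_trend_counts():
    cohort = make_cohort([
        make_icsr("T-1", ["Myalgia"], report_date=date(2021, 1, 1)),
        make_icsr("T-2", ["Myalgia"], report_date=date(2021, 6, 30)),
        make_icsr("T-3", ["Myalgia"], report_date=date(2021, 7, 1)),
        make_icsr("T-4", ["Myalgia"], report_date=date(2023, 2, 1)),
    ])
    df = semester_trend(cohort, date(2021, 1, 1), 5)
    assert list(df.total) == [2, 1, 0, 0, 1]
    empty = make_cohort([])
    assert semester_trend(empty, date(2021, 1, 1), 5).values.sum() == 0
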