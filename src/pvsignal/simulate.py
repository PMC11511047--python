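"""Synthetic spontaneous-report generator with known ground truth.

Emulates a EudraVigilance-style report stream: per analysis group, each
catalog Preferred Term occurs in a report as an independent Bernoulli draw
with a group-specific probability, so the true report-level odds ratio
between any two groups is known exactly:

    OR(pt; A vs B) = [pA/(1-pA)] / [pB/(1-pB)]

On top of the catalog events, each report carries a Poisson number of
background reactions drawn from a fixed pool, demographic/missingness
mixtures, a reporter-qualification mix, a region mix, and a report date
drawn from the group's post-launch semesters with configurable weights
(defaulting to the increasing early-market reporting shape).

The generator is a test harness with calibrated marginals, not an attempt
to fit the joint distribution of any real database.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import add_months
from .io import (
    write_expected_terms,
    write_line_listing,
    write_meddra_map,
)
from .model import (
    AgeGroup,
    ICSR,
    MeddraMap,
    Outcome,
    Reaction,
    Region,
    SeriousnessCriterion,
    Sex,
    SourceQualification,
)

__all__ = [
    "GroupSpec",
    "PTSpec",
    "SimConfig",
    "SimTruth",
    "true_odds_ratio",
    "simulate",
    "default_config",
    "fixture_config",
    "emit_fixture",
    "BACKGROUND_POOL",
    "FALLBACK_PT",
    "SMPC_EXPECTED_TERMS",
]

_OUTCOMES = list(Outcome)  # canonical order for outcome_dist vectors
_NONFATAL_CRITERIA = [
    SeriousnessCriterion.LIFE_THREATENING,
    SeriousnessCriterion.HOSPITALIZATION,
    SeriousnessCriterion.DISABILITY,
    SeriousnessCriterion.OTHER_MEDICALLY_IMPORTANT,
]
_NONFATAL_CRITERIA_W = np.array([0.15, 0.30, 0.10, 0.45])

# Background reactions: common nonspecific PTs, equal draw probability.
BACKGROUND_POOL: list[tuple[str, str]] = [
    ("Nausea", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Headache", "Nervous system disorders"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Insomnia", "Psychiatric disorders"),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders"),
    ("Pruritus", "Skin and subcutaneous tissue disorders"),
    ("Asthenia", "General disorders and administration site conditions"),
    ("Back pain", "Musculoskeletal and connective tissue disorders"),
    ("Cough", "Respiratory, thoracic and mediastinal disorders"),
]
_BACKGROUND_SERIOUS_PROB = 0.05

# Added when a report would otherwise carry no reaction at all.
FALLBACK_PT = ("Background event",
               "General disorders and administration site conditions")

# Index-drug label (SmPC) expected reactions used by the shipped fixture.
SMPC_EXPECTED_TERMS = [
    "Injection site erythema",
    "Injection site pain",
    "Injection site reaction",
    "Injection site rash",
]

_DEFAULT_OUTCOME_DIST = (0.38, 0.17, 0.01, 0.39, 0.01, 0.04)


def _check_prob_vector(name: str, v: Sequence[float], length: int | None = None):
    arr = np.asarray(v, dtype=float)
    if length is not None and arr.size != length:
        raise ValueError(f"{name}: expected {length} entries, got {arr.size}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name}: entries must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities sum to {arr.sum()!r}, not 1")


@dataclass(frozen=True)
class GroupSpec:
    """One simulated analysis group.

    ``drug_mix`` optionally assigns each report a suspect-drug set with the
    given weights (e.g. to emit dual-suspect reports); when omitted every
    report lists ``suspect_drug`` alone.  ``semester_weights`` spread the
    report dates over ``n_semesters`` post-launch semesters.
    """

    name: str
    suspect_drug: str
    launch_date: date
    n_reports: int
    n_semesters: int = 5
    semester_weights: tuple[float, ...] | None = None
    drug_mix: tuple[tuple[tuple[str, ...], float], ...] | None = None

    def __post_init__(self):
        if self.n_reports < 0:
            raise ValueError(f"group {self.name!r}: n_reports must be >= 0")
        if self.n_semesters < 1:
            raise ValueError(f"group {self.name!r}: n_semesters must be >= 1")
        if self.semester_weights is not None:
            w = np.asarray(self.semester_weights, dtype=float)
            if w.size != self.n_semesters:
                raise ValueError(
                    f"group {self.name!r}: {self.n_semesters} semesters but "
                    f"{w.size} weights")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"group {self.name!r}: invalid semester weights")
        if self.drug_mix is not None:
            total = sum(w for _, w in self.drug_mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {self.name!r}: drug_mix weights sum to {total}")
            if any(not drugs for drugs, _ in self.drug_mix):
                raise ValueError(f"group {self.name!r}: empty drug set in drug_mix")

    def weights(self) -> np.ndarray:
        if self.semester_weights is None:
            # increasing early-market reporting shape
            w = np.arange(1, self.n_semesters + 1, dtype=float)
        else:
            w = np.asarray(self.semester_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class PTSpec:
    """One catalog adverse-event term with per-group occurrence probability."""

    pt: str
    soc: str
    prob_per_group: Mapping[str, float]
    serious_prob: float = 0.1
    outcome_dist: tuple[float, ...] = _DEFAULT_OUTCOME_DIST

    def __post_init__(self):
        for g, p in self.prob_per_group.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"PT {self.pt!r}: probability {p} for group {g!r}")
        if not (0.0 <= self.serious_prob <= 1.0):
            raise ValueError(f"PT {self.pt!r}: serious_prob out of [0,1]")
        _check_prob_vector(f"PT {self.pt!r} outcome_dist", self.outcome_dist,
                           len(_OUTCOMES))

    def prob(self, group: str) -> float:
        return float(self.prob_per_group.get(group, 0.0))


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated report stream."""

    seed: int
    groups: tuple[GroupSpec, ...]
    pt_catalog: tuple[PTSpec, ...]
    extra_reactions_mean: float = 1.9
    sex_dist: tuple[float, float] = (0.47, 0.53)  # male, female
    age_dist: tuple[float, ...] = (0.003, 0.003, 0.004, 0.01, 0.50, 0.42, 0.06)
    region_dist: tuple[float, float] = (0.60, 0.40)  # EEA, non-EEA
    source_dist: tuple[float, float] = (0.78, 0.22)  # HCP, non-HCP
    missing_sex_prob: float = 0.03
    missing_age_prob: float = 0.45
    unknown_outcome_prob: float = 0.35
    literature_prob: float = 0.02
    vaccine_prob: float = 0.005
    concomitant_prob: float = 0.35

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.extra_reactions_mean < 0:
            raise ValueError("extra_reactions_mean must be >= 0")
        _check_prob_vector("sex_dist", self.sex_dist, 2)
        _check_prob_vector("age_dist", self.age_dist, len(AgeGroup) - 1)
        _check_prob_vector("region_dist", self.region_dist, 2)
        _check_prob_vector("source_dist", self.source_dist, 2)
        for p_name in ("missing_sex_prob", "missing_age_prob",
                       "unknown_outcome_prob", "literature_prob",
                       "vaccine_prob", "concomitant_prob"):
            p = getattr(self, p_name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{p_name} out of [0,1]")
        pts = [p.pt for p in self.pt_catalog]
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate PT in catalog")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        """Build from a plain mapping (YAML/JSON run configuration)."""
        groups = tuple(
            GroupSpec(
                name=g["name"],
                suspect_drug=g["suspect_drug"],
                launch_date=date.fromisoformat(str(g["launch_date"]))
                if not isinstance(g["launch_date"], date) else g["launch_date"],
                n_reports=int(g["n_reports"]),
                n_semesters=int(g.get("n_semesters", 5)),
                semester_weights=tuple(g["semester_weights"])
                if g.get("semester_weights") else None,
                drug_mix=tuple(
                    (tuple(drugs), float(w)) for drugs, w in g["drug_mix"]
                ) if g.get("drug_mix") else None,
            )
            for g in d["groups"]
        )
        catalog = tuple(
            PTSpec(
                pt=p["pt"],
                soc=p["soc"],
                prob_per_group=dict(p["prob_per_group"]),
                serious_prob=float(p.get("serious_prob", 0.1)),
                outcome_dist=tuple(p.get("outcome_dist", _DEFAULT_OUTCOME_DIST)),
            )
            for p in d["pt_catalog"]
        )
        kwargs = {
            k: d[k]
            for k in (
                "extra_reactions_mean", "missing_sex_prob", "missing_age_prob",
                "unknown_outcome_prob", "literature_prob", "vaccine_prob",
                "concomitant_prob",
            )
            if k in d
        }
        for k in ("sex_dist", "age_dist", "region_dist", "source_dist"):
            if k in d:
                kwargs[k] = tuple(d[k])
        return cls(seed=int(d["seed"]), groups=groups, pt_catalog=catalog, **kwargs)


def true_odds_ratio(p_a: float, p_b: float) -> float:
    """Report-level odds ratio implied by two occurrence probabilities.

    Returns ``inf`` when non-estimable in the disproportionate direction
    (pA = 1 or pB = 0 with pA > 0), 0.0 when the index odds vanish, and
    ``nan`` when both degenerate.
    """
    if p_a == p_b:
        return 1.0
    a_deg = p_a in (0.0, 1.0)
    b_deg = p_b in (0.0, 1.0)
    if a_deg and b_deg:
        return math.nan
    if p_a == 1.0 or p_b == 0.0:
        return math.inf
    if p_a == 0.0 or p_b == 1.0:
        return 0.0
    return (p_a / (1 - p_a)) / (p_b / (1 - p_b))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated stream: configured probabilities, the
    implied pairwise true odds ratios, and expected reports per semester."""

    seed: int
    pt_probs: tuple[tuple[str, str, tuple[tuple[str, float], ...]], ...]
    true_or: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    expected_per_semester: tuple[tuple[str, tuple[float, ...]], ...]

    def or_of(self, pt: str, pair: str) -> float:
        for name, pairs in self.true_or:
            if name == pt:
                return dict(pairs)[pair]
        raise KeyError(pt)

    def to_json_dict(self) -> dict:
        probs = {pt: dict(p) for pt, _, p in self.pt_probs}
        socs = {pt: soc for pt, soc, _ in self.pt_probs}
        return {
            "seed": self.seed,
            "pts": [
                {
                    "pt": pt,
                    "soc": socs[pt],
                    "prob": probs[pt],
                    "true_or": {
                        pair: ("inf" if math.isinf(v) else v)
                        for pair, v in dict(dict(self.true_or)[pt]).items()
                    },
                }
                for pt, _, _ in self.pt_probs
            ],
            "groups": [
                {"name": g, "expected_reports_per_semester": list(exp)}
                for g, exp in self.expected_per_semester
            ],
        }


def _build_truth(config: SimConfig) -> SimTruth:
    pairs = [
        (a.name, b.name)
        for a in config.groups
        for b in config.groups
        if a.name != b.name
    ]
    pt_probs = tuple(
        (p.pt, p.soc, tuple((g.name, p.prob(g.name)) for g in config.groups))
        for p in config.pt_catalog
    )
    true_or = tuple(
        (
            p.pt,
            tuple(
                (f"{ga}_vs_{gb}", true_odds_ratio(p.prob(ga), p.prob(gb)))
                for ga, gb in pairs
            ),
        )
        for p in config.pt_catalog
    )
    expected = tuple(
        (g.name, tuple(float(g.n_reports) * w for w in g.weights()))
        for g in config.groups
    )
    return SimTruth(seed=config.seed, pt_probs=pt_probs, true_or=true_or,
                    expected_per_semester=expected)


def _semester_bounds(launch: date, k: int) -> tuple[date, date]:
    return add_months(launch, 6 * (k - 1)), add_months(launch, 6 * k)


def _draw_reaction(rng: np.random.Generator, pt: str, serious_prob: float,
                   outcome_dist: Sequence[float],
                   unknown_outcome_prob: float) -> Reaction:
    if rng.random() < unknown_outcome_prob:
        outcome = Outcome.UNKNOWN
    else:
        outcome = _OUTCOMES[int(rng.choice(len(_OUTCOMES), p=np.asarray(outcome_dist)))]
    if outcome is Outcome.FATAL:
        criteria = frozenset({SeriousnessCriterion.DEATH})
    elif rng.random() < serious_prob:
        idx = int(rng.choice(len(_NONFATAL_CRITERIA),
                             p=_NONFATAL_CRITERIA_W / _NONFATAL_CRITERIA_W.sum()))
        criteria = frozenset({_NONFATAL_CRITERIA[idx]})
    else:
        criteria = frozenset()
    duration = float(rng.integers(0, 61)) if rng.random() < 0.3 else None
    return Reaction(pt=pt, outcome=outcome, seriousness_criteria=criteria,
                    duration_days=duration)


def simulate(config: SimConfig) -> tuple[list[ICSR], MeddraMap, SimTruth]:
    """Generate the report stream described by ``config``.

    Fully reproducible from ``config.seed``; the MedDRA map returned covers
    every catalog, background and fallback PT.
    """
    truth = _build_truth(config)  # validates nothing extra; config already checked
    rng = np.random.default_rng(config.seed)

    mapping = {p.pt: p.soc for p in config.pt_catalog}
    for pt, soc in BACKGROUND_POOL + [FALLBACK_PT]:
        mapping.setdefault(pt, soc)
    meddra = MeddraMap(mapping, version_label="synthetic")

    sexes = [Sex.MALE, Sex.FEMALE]
    ages = [a for a in AgeGroup if a is not AgeGroup.NOT_SPECIFIED]
    regions = [Region.EEA, Region.NON_EEA]
    sources = [SourceQualification.HEALTHCARE_PROFESSIONAL,
               SourceQualification.NON_HEALTHCARE_PROFESSIONAL]

    collection: list[ICSR] = []
    for group in config.groups:
        n = group.n_reports
        if n == 0:
            continue
        probs = np.array([p.prob(group.name) for p in config.pt_catalog])
        occ = rng.random((n, len(config.pt_catalog))) < probs
        n_extra = rng.poisson(config.extra_reactions_mean, size=n)
        weights = group.weights()
        sem = rng.choice(group.n_semesters, size=n, p=weights) + 1
        sem_bounds = [_semester_bounds(group.launch_date, k)
                      for k in range(1, group.n_semesters + 1)]

        for i in range(n):
            reactions: list[Reaction] = []
            for j, spec in enumerate(config.pt_catalog):
                if occ[i, j]:
                    reactions.append(_draw_reaction(
                        rng, spec.pt, spec.serious_prob, spec.outcome_dist,
                        config.unknown_outcome_prob))
            # background draws never repeat a PT already in the report
            present = {r.pt for r in reactions}
            available = [jj for jj, (pt, _) in enumerate(BACKGROUND_POOL)
                         if pt not in present]
            k = min(int(n_extra[i]), len(available))
            if k > 0:
                picks = rng.choice(len(available), size=k, replace=False)
                for jj in picks:
                    pt, _soc = BACKGROUND_POOL[available[int(jj)]]
                    reactions.append(_draw_reaction(
                        rng, pt, _BACKGROUND_SERIOUS_PROB, _DEFAULT_OUTCOME_DIST,
                        config.unknown_outcome_prob))
            if not reactions:
                reactions.append(_draw_reaction(
                    rng, FALLBACK_PT[0], _BACKGROUND_SERIOUS_PROB,
                    _DEFAULT_OUTCOME_DIST, config.unknown_outcome_prob))

            start, end = sem_bounds[int(sem[i]) - 1]
            span = (end - start).days
            report_date = start + timedelta(days=int(rng.integers(0, span)))

            if group.drug_mix is not None:
                w = np.array([wt for _, wt in group.drug_mix])
                pick = int(rng.choice(len(group.drug_mix), p=w / w.sum()))
                suspects = set(group.drug_mix[pick][0])
            else:
                suspects = {group.suspect_drug}
            if rng.random() < config.vaccine_prob:
                suspects.add("covid-19 vaccine")
            concomitant = (
                {"atorvastatin"} if rng.random() < config.concomitant_prob else set()
            )

            sex = (Sex.UNKNOWN if rng.random() < config.missing_sex_prob
                   else sexes[int(rng.choice(2, p=np.asarray(config.sex_dist)))])
            age = (AgeGroup.NOT_SPECIFIED
                   if rng.random() < config.missing_age_prob
                   else ages[int(rng.choice(len(ages), p=np.asarray(config.age_dist)))])

            collection.append(ICSR(
                case_id=f"{group.name.upper()}-{i + 1:06d}",
                report_date=report_date,
                source_qualification=sources[
                    int(rng.choice(2, p=np.asarray(config.source_dist)))],
                sex=sex,
                age_group=age,
                region=regions[int(rng.choice(2, p=np.asarray(config.region_dist)))],
                suspect_drugs=frozenset(suspects),
                concomitant_drugs=frozenset(concomitant),
                reactions=tuple(reactions),
                from_literature=bool(rng.random() < config.literature_prob),
            ))
    return collection, meddra, truth


def _paper_scale_catalog(index: str, reference: str) -> tuple[PTSpec, ...]:
    # (pt, soc, p_index, p_reference, serious_prob)
    rows = [
        ("Myalgia", "Musculoskeletal and connective tissue disorders",
         0.175, 0.080, 0.08),
        ("Pain in extremity", "Musculoskeletal and connective tissue disorders",
         0.0426, 0.0279, 0.08),
        ("Low density lipoprotein increased", "Investigations",
         0.158, 0.0155, 0.05),
        ("Blood cholesterol increased", "Investigations", 0.0337, 0.0088, 0.05),
        ("Weight increased", "Investigations", 0.0231, 0.0098, 0.05),
        ("Liver function test increased", "Investigations", 0.0231, 0.0017, 0.20),
        ("Drug ineffective",
         "General disorders and administration site conditions",
         0.0906, 0.0154, 0.05),
        ("Injection site erythema",
         "General disorders and administration site conditions",
         0.0622, 0.0126, 0.02),
        ("Injection site pain",
         "General disorders and administration site conditions",
         0.0480, 0.0315, 0.02),
        ("Drug intolerance",
         "General disorders and administration site conditions",
         0.0231, 0.0045, 0.10),
        ("Nasopharyngitis", "Infections and infestations", 0.02, 0.02, 0.05),
        ("Dizziness", "Nervous system disorders", 0.025, 0.02, 0.10),
        ("Myocardial infarction", "Cardiac disorders", 0.0, 0.02, 0.80),
        ("Angina pectoris", "Cardiac disorders", 0.0, 0.01, 0.50),
        ("Pneumonia", "Infections and infestations", 0.0, 0.015, 0.60),
    ]
    return tuple(
        PTSpec(pt=pt, soc=soc, prob_per_group={index: pa, reference: pb},
               serious_prob=sp)
        for pt, soc, pa, pb, sp in rows
    )


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale default: 563 index reports over 5 semesters vs 14,673
    reference reports over 17 semesters, catalog rates set to the observed
    index frequencies and reference rates implied by the screened odds
    ratios, with one exact-null term (Nasopharyngitis) and three
    reference-only terms."""
    groups = (
        GroupSpec(
            name="inclisiran", suspect_drug="inclisiran",
            launch_date=date(2021, 1, 1), n_reports=563, n_semesters=5,
            semester_weights=(0.10, 0.14, 0.19, 0.25, 0.32),
        ),
        GroupSpec(
            name="pcsk9a", suspect_drug="evolocumab",
            launch_date=date(2015, 1, 1), n_reports=14673, n_semesters=17,
            semester_weights=(1, 1.5, 2, 2.5, 3) + (5,) * 12,
            drug_mix=(
                (("evolocumab",), 0.652),
                (("alirocumab",), 0.342),
                (("evolocumab", "alirocumab"), 0.006),
            ),
        ),
    )
    return SimConfig(
        seed=seed,
        groups=groups,
        pt_catalog=_paper_scale_catalog("inclisiran", "pcsk9a"),
    )


def fixture_config(seed: int = 20210101) -> SimConfig:
    """Canonical small fixture: two groups, 12 catalog PTs spanning 6 SOCs,
    pinned seed; scaled down for fast tests."""
    full = {p.pt: p for p in _paper_scale_catalog("inclisiran", "pcsk9a")}
    keep = [
        "Myalgia", "Pain in extremity",
        "Low density lipoprotein increased", "Blood cholesterol increased",
        "Liver function test increased",
        "Drug ineffective", "Injection site erythema", "Drug intolerance",
        "Nasopharyngitis", "Dizziness",
        "Myocardial infarction", "Pneumonia",
    ]
    groups = (
        GroupSpec(
            name="inclisiran", suspect_drug="inclisiran",
            launch_date=date(2021, 1, 1), n_reports=160, n_semesters=5,
            semester_weights=(0.10, 0.14, 0.19, 0.25, 0.32),
        ),
        GroupSpec(
            name="pcsk9a", suspect_drug="evolocumab",
            launch_date=date(2015, 1, 1), n_reports=640, n_semesters=17,
            semester_weights=(1, 1.5, 2, 2.5, 3) + (5,) * 12,
            drug_mix=(
                (("evolocumab",), 0.652),
                (("alirocumab",), 0.342),
                (("evolocumab", "alirocumab"), 0.006),
            ),
        ),
    )
    return SimConfig(seed=seed, groups=groups,
                     pt_catalog=tuple(full[k] for k in keep))


def emit_fixture(outdir: str | Path, config: SimConfig | None = None) -> dict[str, Path]:
    """Write the canonical fixture files; byte-stable across runs.

    Emits ``line_listing.csv``, ``meddra_map.tsv``, ``expected_terms.txt``
    and ``truth.json`` under ``outdir`` and returns their paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or fixture_config()
    collection, meddra, truth = simulate(config)
    paths = {
        "line_listing": outdir / "line_listing.csv",
        "meddra_map": outdir / "meddra_map.tsv",
        "expected_terms": outdir / "expected_terms.txt",
        "truth": outdir / "truth.json",
    }
    write_line_listing(collection, paths["line_listing"])
    write_meddra_map(meddra, paths["meddra_map"])
    write_expected_terms(SMPC_EXPECTED_TERMS, paths["expected_terms"])
    with paths["truth"].open("w", encoding="utf-8", newline="") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
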