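# Methods

## The analysis model

The package implements case-level disproportionality screening of
spontaneous adverse-reaction reports. The unit of analysis is the ICSR
(one report, one patient, one or more coded reactions), never the
individual reaction: a report counts once toward a term however many of
its reactions carry that Preferred Term (or, at SOC level, map to that
System Organ Class). This matters for every denominator in the package —
characteristics tables, per-SOC frequencies and all 2×2 contingency cells
are case counts.

For a term the 2×2 table (index cases with/without the term vs reference
cases with/without it) yields the crude reporting odds ratio
ROR = ad/bc with the Woolf (log-normal) confidence interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964. Woolf is the standard
pharmacovigilance interval for crude RORs; no continuity correction is
applied — a zero cell makes the estimate non-estimable and is reported as
such rather than inflated, which is safe here because screening already
requires a ≥ 3 index cases, and reference-only terms (a = 0, c > 0) are
listed separately without an ROR. Positive significance means lower CI
bound > 1, negative means upper bound < 1. No multiplicity adjustment is
made across terms; the robustness criterion (significant in both the full
and the time-normalized comparison) is the screen's only guard against
spurious positives, mirroring common practice for crude-ROR screens.

The minimum-case filter applies to the index-group count *a*: the screen
exists to characterise the drug under study, so "reported in at least
three ICSRs" is read against that drug, and reference-only terms are
surfaced in their own list instead of being forced through the filter.

## Time-based normalization

Reference drugs marketed years before the index drug accumulate reports
under a different reporting climate (the Weber effect: early-market years
over-report, especially non-serious events). The pipeline therefore
re-runs every comparison against the reference cohort restricted to its
first 30 post-launch months — the same market exposure the index drug had.
Month arithmetic is calendar-based with day-of-month clamping, and the
normalization window is half-open, `[launch, launch + months)`, so a
launch on 2015-01-01 with 30 months keeps reports through 2017-06-30
inclusive. Semesters are defined the same way
(`[launch + 6(k−1) months, launch + 6k months)`), making the 30-month
window exactly semesters 1–5.

The index group's observation window, by contrast, is a hard configured
pair of dates (e.g. 2021-01-01 to 2023-06-30), because inclusion windows
for a retrospective extract are fixed editorially, not derived.

## Descriptive conventions

- **Global outcome per case**: worst outcome dominates, with the total
  order Fatal > Not recovered > Recovered with sequelae >
  Recovering > Recovered > Unknown; Unknown results only when every
  reaction's outcome is Unknown. This is the conservative reading of
  "lower level of resolution" outcome aggregation: any definite
  information beats Unknown, and worse definite information beats better.
- **Denominators**: sex, dichotomized age (<65 / ≥65) and global outcome
  are reported as percentages of the *known* values, with the Unknown row
  carrying the whole-cohort denominator; seriousness, reporter
  qualification and region are percentages of the whole cohort. These are
  the conventions under which the bundled worked example reproduces its
  published column exactly (e.g. 4 fatal / 303 known outcomes → 1.3%, and
  351 unknown ages / 563 → 62.3%).
- **Chi-square**: two-tailed Pearson, no continuity correction, computed
  on known categories only. Each category also gets its own 2×2 test
  (category vs the other known categories) across cohorts — this is what
  published tables print when different rows of one variable carry
  different p-values — alongside a per-variable omnibus test. A zero
  margin raises an error naming the category rather than emitting NaN
  silently.
- **Rounding**: percentages and means are rounded half-up to 1 decimal,
  RORs and CI bounds half-up to 2 decimals, matching the precision such
  tables are printed at. Internal computation is double precision
  throughout; rounding happens only at the reporting edge.
- **Dual-suspect reports** (both reference antibodies suspect) join the
  reference cohort once and are labelled "both"; they never inflate the
  per-drug subgroup counts. This is the only rule under which the worked
  example's subgroup totals (9,562 + 5,016 + 95 = 14,673) reconcile.
- **Unmapped PTs** fall into a sentinel "Unmapped" SOC with a one-time
  warning instead of being dropped, so dictionary gaps can never shrink a
  denominator silently.

## The synthetic generator

`pvsignal.simulate` emulates the data structure the analysis assumes, with
enough realism to make every downstream stage testable and its statistics
checkable against known truth:

- **Occurrence model**: each catalog PT occurs in a report as an
  independent Bernoulli draw with a group-specific probability, at most
  once per report. The true report-level odds ratio between groups is then
  known in closed form, which is what the coverage and null-calibration
  tests consume. No co-occurrence structure is modelled — the screening
  statistic is case-marginal, so none is needed for calibration.
- **Background reactions**: a Poisson(λ) number of extra reactions per
  report drawn without replacement from a 12-term pool of nonspecific PTs
  (never duplicating a PT already in the report), plus a fallback
  "Background event" reaction when a report would otherwise be empty. The
  expected reactions-per-report is therefore
  Σp + λ + P(no catalog PT)·e^(−λ), and the calibration test asserts
  against that exact expression.
- **Study-scale defaults** (`default_config()`): 563 index reports over 5
  post-launch semesters vs 14,673 reference reports over 17, reference
  subgroup mix 65.2/34.2/0.6% (evolocumab/alirocumab/both), catalog
  occurrence rates set to the observed index frequencies of the motivating
  comparison (e.g. myalgia 17.5% vs 8.0%) with one exact-null term
  (Nasopharyngitis, equal rates) and three reference-only terms
  (myocardial infarction, pneumonia, angina pectoris), λ = 1.9 so mean
  reactions per report lands near 2.5, missingness ~3% for sex, 45% for
  age, 35% unknown outcomes, and an increasing semester-weight shape.
  Sex/age/outcome missingness are single global rates; the real
  comparison's groups differ on these (62% vs 38% missing age), so the
  defaults sit between them — per-group missingness was judged not worth
  the configuration surface since no test depends on it.
- **The canonical fixture** (`fixture_config()` / `emit_fixture()`):
  the same structure scaled to 160 + 640 reports with 12 catalog PTs
  spanning 6 SOCs and a pinned seed; it is byte-stable across runs and is
  what the pipeline determinism tests and the CLI default use.

Deviations from a flat generator configuration were made where one value
could not describe both groups: semester weights and counts are per group
(5 vs 17 semesters of market history), the reference group takes a
weighted suspect-drug mix to produce dual-suspect reports, and small
literature/vaccine probabilities exist so the exclusion stage is
exercised end to end.

What passing tests on this generator do **not** show: realism of joint
distributions (age × seriousness, term co-occurrence, duplicate
reporting), reporting-rate dynamics beyond the configured semester
weights, or anything about dictionary versioning. The generator is a test
harness, not a database emulator.

## Worked-example reconstruction

Published safety tables print marginal counts, not line listings.
`pvsignal.worked` rebuilds cohorts whose univariate margins equal the
printed ones (563 index reports with 141 serious, 4 fatal among 303 known
outcomes, 99 myalgia cases, 1,468 reactions; 14,673 reference reports of
which 1,717 fall in the first 30 post-launch months, with 1,174 myalgia
cases — the printed 8.0% share rounded to a count). Variables are
assigned independently by report position, which is sufficient because
every quantity read back from the reconstruction is a univariate margin
or a 2×2 built from such margins. The reconstruction is deterministic.
The reference myalgia cell is itself reconstructed from a printed
percentage, so ROR/CI checks against it are consistency checks at
reconstruction-rounding accuracy (±0.05 on the point estimate, ±0.1 on
the bounds), not exact reproductions.

## Numerical and testing choices

- Monte-Carlo checks of the significance rule draw the 2×2 cell counts
  directly as Binomial(n, p) per group, which under the generator's
  independent-Bernoulli occurrence model is distribution-identical to
  full report simulation and keeps 1,000-replicate runs in seconds; the
  full generator path is exercised separately (determinism, empirical
  rates, round trips, end-to-end runs). Problem sizes used: 2,000 reports
  per group, 1,000 replicates for calibration/coverage; 40 replicates of
  2,000 reports for the reactions-per-report calibration; 10,000 random
  tables for the algebraic CI identities.
- The Woolf implementation is cross-checked against closed forms (the
  geometric-mean identity √(lo·hi) = ROR, antisymmetry under cohort swap)
  and the chi-square against both its 2×2 closed form and an independent
  library implementation.
- Ties in the signal table are broken alphabetically by term after the
  primary sort (decreasing normalized ROR, non-estimable last).
- Degenerate inputs: empty cohorts are rejected by the descriptive stage
  with a clear error; a simulation probability of exactly 0 or 1 makes
  the true OR 0/∞ and is flagged non-estimable in the truth object rather
  than propagated as a float overflow.

## Known limitations

Crude RORs only — no stratification, no Bayesian shrinkage (IC, EBGM),
no PRR, by design. The line-listing dialect is this package's own stable
CSV format, not a scrape of any portal's export; users of real extracts
must map their columns to it. Expectedness is a flat PT list from the
product label; no hierarchy-aware matching is attempted. The vaccine
exclusion recognises vaccines by substance name, since the dialect
carries no dedicated flag.
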