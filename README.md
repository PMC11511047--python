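# pvsignal

Cohort construction, descriptive comparison and reporting-odds-ratio (ROR)
disproportionality screening for spontaneous adverse-drug-reaction reports
(ICSRs), in the style of a EudraVigilance line-listing analysis.

The package is written for pharmacovigilance analysts and biostatisticians
who want a tested, scriptable version of the classic post-marketing safety
workflow: take an individual-case-safety-report line listing for a newly
marketed drug (the motivating use case is inclisiran, an siRNA PCSK9
inhibitor) and a longer-established comparator class (the PCSK9 monoclonal
antibodies evolocumab and alirocumab), and ask which adverse-event terms
are reported disproportionately often for the new drug.

## What it computes

For a term *t* (a MedDRA Preferred Term, or a System Organ Class after
aggregation) the case-level 2×2 table against the reference cohort is

|           | with *t* | without *t* |
|-----------|----------|-------------|
| index     | a        | b           |
| reference | c        | d           |

and the crude reporting odds ratio with its Woolf 95% confidence interval is

```
ROR = (a·d)/(b·c),   CI = exp( ln ROR ± z · √(1/a + 1/b + 1/c + 1/d) ),  z = 1.959964
```

A term is a positive signal when the lower CI bound exceeds 1, and is only
screened when reported in at least three index cases. Because the
comparator has been on the market longer, every screen is run twice: against
the full reference cohort and against a *time-normalized* one restricted to
the reference drugs' first 30 post-launch months (the same market exposure
as the index drug), which guards against reporting-era artefacts such as
the Weber effect. A signal is called **robust** only when positive in both.

Around that core the package provides:

- `pvsignal.model` / `pvsignal.io` — typed ICSR/reaction/MedDRA-map domain
  objects and readers/writers for the line-listing CSV dialect, PT→SOC TSV
  and expected-terms (SmPC) files;
- `pvsignal.cohort` — literature/vaccine exclusions, group assignment with
  dual-suspect handling, observation windows, calendar semesters and the
  30-month normalization;
- `pvsignal.descriptive` — the characteristics table (sex, age <65/≥65,
  seriousness, worst-case global outcome, reporter qualification, region)
  with the field's denominator conventions and two-tailed Pearson
  chi-square comparisons, semester reporting trends, per-SOC report
  frequencies and reactions-per-report summaries;
- `pvsignal.disproportionality` — contingency building, Woolf RORs,
  significance classification, SmPC expectedness annotation and the
  full/normalized dual screen;
- `pvsignal.simulate` — a synthetic report generator with known per-group
  occurrence probabilities (hence known true odds ratios) so the whole
  pipeline is testable without access to any real database;
- `pvsignal.pipeline` / the `pvsignal` CLI — end-to-end orchestration with
  plain-file stage outputs and a flow ledger accounting for every input
  report.

## Worked example

The package ships a deterministic reconstruction of a published
inclisiran-vs-PCSK9-antibody comparison (563 index reports, 14,673
reference reports, rebuilt from the printed marginal counts):

```python
from pvsignal.worked import worked_index_cohort, worked_reference_cohort
from pvsignal.cohort import normalize_window
from pvsignal.descriptive import characteristics_table
from pvsignal.disproportionality import Level, ror_woolf, term_contingency

index = worked_index_cohort()            # 563 reports
reference = worked_reference_cohort()    # 14,673 reports
ref_norm = normalize_window(reference, 30)   # 1,717 reports

table = characteristics_table(index, ref_norm)
row = table.lookup("seriousness", "Serious", "inclisiran")
print(row["count"], row["pct"])          # -> 141 25.0

t = term_contingency(index, reference, "Myalgia", Level.PT)
print(t)                                  # -> ContingencyTable(a=99, b=464, c=1174, d=13499)
print(ror_woolf(t))                       # -> (2.4533..., 1.9589..., 3.0724...)
```

So 25.0% of index reports are serious, and myalgia is reported with
ROR 2.45 (95% CI 1.96–3.07) against the full reference cohort: the odds of
a myalgia report are about two and a half times higher for the index drug,
with a confidence interval excluding 1 (a positive signal).

A fully synthetic end-to-end run:

```bash
pvsignal simulate --out fixture/
pvsignal run-all --config run.yaml      # paths + group definitions, see tests/test_pipeline.py
```

writes the exclusion log, cohort membership, characteristics tables (full,
normalized, and EEA-only), semester trends, SOC frequencies, PT/SOC signal
tables with expectedness and robustness flags, reference-only terms, and a
`summary.json` whose flow ledger accounts for 100% of the input reports.

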