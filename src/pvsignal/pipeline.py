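"""End-to-end orchestration: exclusions -> cohorts -> descriptives -> signals.

Every stage writes a plain file under the output directory so any stage can
be audited or re-run in isolation, and a ``summary.json`` carries row
counts plus a flow ledger accounting for every input report exactly once
(excluded, out-of-window, unassigned, or cohort member).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    GroupDefinition,
    apply_exclusions,
    build_cohort,
    normalize_window,
    overlap_warning,
    semester_index,
)
from .descriptive import (
    CharacteristicsTable,
    characteristics_table,
    reactions_per_icsr,
    semester_trend,
    soc_frequencies,
)
from .disproportionality import Level, Z_95, screen
from .io import read_expected_terms, read_line_listing, read_meddra_map
from .model import ICSR

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all", "filter_cohort", "subset_rerun"]

SUMMARY_SCHEMA_VERSION = 1

_FILTERABLE_FIELDS = {
    "region": lambda m: m.region.short_label,
    "sex": lambda m: m.sex.label,
    "source_qualification": lambda m: m.source_qualification.label,
    "age_group": lambda m: m.age_group.label,
}


class PipelineError(RuntimeError):
    """Stage failure, prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Run configuration for the full pipeline."""

    line_listing: Path
    meddra_map: Path
    expected_terms: Path
    outdir: Path
    groups: tuple[GroupDefinition, ...]
    index_group: str
    reference_group: str
    normalization_months: int = 30
    min_cases: int = 3
    z: float = Z_95
    strict: bool = False
    subset: tuple[str, tuple[str, ...]] | None = None  # (field, allowed values)

    def __post_init__(self):
        names = {g.name for g in self.groups}
        for role, name in (("index_group", self.index_group),
                           ("reference_group", self.reference_group)):
            if name not in names:
                raise ValueError(f"{role} {name!r} is not a defined group")
        if self.normalization_months <= 0:
            raise ValueError("normalization_months must be positive")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping, base_dir: Path | None = None) -> "RunConfig":
        base = Path(base_dir) if base_dir else Path(".")

        def p(key):
            return (base / d["paths"][key]).resolve()

        groups = tuple(
            GroupDefinition(
                name=g["name"],
                suspect_drugs=frozenset(g["suspect_drugs"]),
                launch_date=_as_date(g["launch_date"]),
                window_start=_as_date(g["window_start"]),
                window_end=_as_date(g["window_end"]),
            )
            for g in d["groups"]
        )
        subset = None
        if d.get("subset"):
            (fld, vals), = d["subset"].items()
            subset = (fld, tuple([vals] if isinstance(vals, str) else vals))
        return cls(
            line_listing=p("line_listing"),
            meddra_map=p("meddra_map"),
            expected_terms=p("expected_terms"),
            outdir=(base / d["paths"]["outdir"]).resolve(),
            groups=groups,
            index_group=d["index_group"],
            reference_group=d["reference_group"],
            normalization_months=int(d.get("normalization_months", 30)),
            min_cases=int(d.get("min_cases", 3)),
            z=float(d.get("z", Z_95)),
            strict=bool(d.get("strict", False)),
            subset=subset,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d, base_dir=path.parent)


def _as_date(v) -> date:
    return v if isinstance(v, date) else date.fromisoformat(str(v))


def filter_cohort(cohort: Cohort, field_name: str, values: Sequence[str]) -> Cohort:
    """Keep members whose ``field_name`` equals one of ``values``."""
    try:
        extract = _FILTERABLE_FIELDS[field_name]
    except KeyError:
        raise ValueError(
            f"unknown subset field {field_name!r}; "
            f"choose from {sorted(_FILTERABLE_FIELDS)}") from None
    allowed = set(values)
    pairs = [
        (m, lab)
        for m, lab in zip(cohort.members, cohort.subgroup_labels)
        if extract(m) in allowed
    ]
    return Cohort(cohort.name, cohort.definition,
                  tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def subset_rerun(index: Cohort, reference: Cohort, field_name: str,
                 values: Sequence[str]) -> CharacteristicsTable:
    """Re-run the descriptive comparison on a filtered subset of both cohorts."""
    return characteristics_table(
        filter_cohort(index, field_name, values),
        filter_cohort(reference, field_name, values),
    )


def _flow_ledger(collection: list[ICSR], exclusions, cohorts: list[Cohort]) -> dict:
    member_ids = set()
    for c in cohorts:
        member_ids |= c.case_ids
    excluded_ids = {e.case_id for e in exclusions}
    reason_counts: dict[str, int] = {}
    for e in exclusions:
        for r in e.reasons:
            reason_counts[r] = reason_counts.get(r, 0) + 1
    drug_universe = frozenset().union(*(c.definition.suspect_drugs for c in cohorts))
    out_of_window = 0
    unassigned = 0
    for icsr in collection:
        if icsr.case_id in excluded_ids or icsr.case_id in member_ids:
            continue
        if icsr.suspect_drugs & drug_universe:
            out_of_window += 1
        else:
            unassigned += 1
    ledger = {
        "input": len(collection),
        "excluded": len(excluded_ids),
        "exclusion_reasons": reason_counts,
        "members": len(member_ids),
        "out_of_window": out_of_window,
        "unassigned": unassigned,
    }
    assert (ledger["excluded"] + ledger["members"] + out_of_window + unassigned
            == len(collection)), "flow ledger does not balance"
    return ledger


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write all tables under ``config.outdir``.

    Returns the run summary (also written as ``summary.json``).  Raises
    :class:`PipelineError` naming the failing stage; nothing is written if
    the inputs cannot be read.
    """
    # -- stage: inputs ----------------------------------------------------
    for p in (config.line_listing, config.meddra_map, config.expected_terms):
        if not Path(p).exists():
            raise PipelineError(f"inputs: missing file {p}")
    try:
        collection = read_line_listing(config.line_listing, strict=config.strict)
        meddra = read_meddra_map(config.meddra_map)
        expected = read_expected_terms(config.expected_terms)
    except Exception as e:
        raise PipelineError(f"inputs: {e}") from e

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise PipelineError(f"{name}: {e}") from e

    # -- stage: exclusions ------------------------------------------------
    kept, exclusions = stage("exclusions", apply_exclusions, collection)
    pd.DataFrame(
        [{"case_id": e.case_id, "reasons": "+".join(e.reasons)} for e in exclusions],
        columns=["case_id", "reasons"],
    ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)

    # -- stage: cohorts ---------------------------------------------------
    cohorts = {g.name: stage("cohorts", build_cohort, kept, g) for g in config.groups}
    overlaps = overlap_warning(list(cohorts.values()))
    index = cohorts[config.index_group]
    reference = cohorts[config.reference_group]
    reference_norm = stage("normalization", normalize_window, reference,
                           config.normalization_months)
    if len(index) == 0 or len(reference) == 0:
        raise PipelineError("cohorts: empty index or reference cohort")
    pd.DataFrame(
        [
            {"cohort": c.name, "case_id": m.case_id, "subgroup": lab}
            for c in cohorts.values()
            for m, lab in zip(c.members, c.subgroup_labels)
        ]
    ).to_csv(outdir / "cohort_members.tsv", sep="\t", index=False)

    # -- stage: descriptive -----------------------------------------------
    chars_full = stage("descriptive", characteristics_table, index, reference)
    chars_norm = stage("descriptive", characteristics_table, index, reference_norm)
    chars_full.to_tsv(outdir / "characteristics_full.tsv")
    chars_norm.to_tsv(outdir / "characteristics_normalized.tsv")

    eea_tables = {}
    for label, ref in (("full", reference), ("normalized", reference_norm)):
        try:
            t = subset_rerun(index, ref, "region", ["EEA"])
            t.to_tsv(outdir / f"characteristics_eea_{label}.tsv")
            eea_tables[label] = t
        except ValueError as e:
            logger.warning("EEA subset re-run (%s) skipped: %s", label, e)

    trends = {}
    for c in (index, reference):
        launch = c.definition.launch_date
        n_sem = semester_index(c.definition.window_end, launch)
        trends[c.name] = stage("trend", semester_trend, c, launch, n_sem)
        trends[c.name].to_csv(outdir / f"semester_trend_{c.name}.tsv", sep="\t")

    socs = {}
    for c in (index, reference, reference_norm):
        key = c.name if c is not reference_norm else f"{c.name}_normalized"
        socs[key] = stage("soc", soc_frequencies, c, meddra)
        socs[key].to_csv(outdir / f"soc_frequencies_{key}.tsv", sep="\t", index=False)

    # -- stage: signals ---------------------------------------------------
    screens = {}
    for level in (Level.PT, Level.SOC):
        res = stage("signals", screen, index, reference, reference_norm, level,
                    meddra, expected, config.min_cases, config.z)
        screens[level.value] = res
        res.to_frame().to_csv(outdir / f"signals_{level.value}.tsv", sep="\t",
                              index=False, float_format="%.6g")
        pd.DataFrame(res.reference_only, columns=["term", "n_reference"]).to_csv(
            outdir / f"reference_only_{level.value}.tsv", sep="\t", index=False)

    # -- summary ----------------------------------------------------------
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "flow_ledger": _flow_ledger(collection, exclusions, list(cohorts.values())),
        "cohorts": {
            name: {"n": len(c), "subgroups": c.subgroup_counts()}
            for name, c in cohorts.items()
        },
        "reference_normalized": {
            "n": len(reference_norm),
            "subgroups": reference_norm.subgroup_counts(),
        },
        "overlapping_case_ids": overlaps,
        "reactions_per_icsr": {
            "index": reactions_per_icsr(index),
            "reference": reactions_per_icsr(reference),
        },
        "signals": {
            lvl: {
                "n_rows": len(res.rows),
                "n_reference_only": len(res.reference_only),
                "robust_terms": sorted({
                    r.term for r in res.rows if r.robust
                }),
            }
            for lvl, res in screens.items()
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "summary.json"),
    }
    with (outdir / "summary.json").open("w", encoding="utf-8", newline="") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
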