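"""Readers and writers for the line-listing, MedDRA-map and expected-terms files.

Line-listing dialect: UTF-8 CSV with RFC 4180 quoting and a fixed column
order.  Each row is one ICSR; the ``reactions`` field packs the per-reaction
records as ";"-joined blocks of the form::

    PT (duration - outcome - seriousness)

where ``duration`` is a day count or ``n/a``, ``outcome`` is one of the six
standard outcome labels, and ``seriousness`` is ``No`` or a ","-joined list
of seriousness-criterion labels.
"""

from __future__ import annotations

import csv
import logging
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    AgeGroup,
    ExpectedTerms,
    ICSR,
    MeddraMap,
    Outcome,
    Reaction,
    Region,
    SeriousnessCriterion,
    Sex,
    SourceQualification,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LineListingError",
    "COLUMNS",
    "format_reaction",
    "parse_reaction",
    "read_line_listing",
    "write_line_listing",
    "read_meddra_map",
    "write_meddra_map",
    "read_expected_terms",
    "write_expected_terms",
]

COLUMNS = [
    "case_id",
    "report_date",
    "source_qualification",
    "sex",
    "age_group",
    "region",
    "from_literature",
    "suspect_drugs",
    "concomitant_drugs",
    "reactions",
]

# canonical serialization order for seriousness criteria
_CRITERIA_ORDER = list(SeriousnessCriterion)


class LineListingError(ValueError):
    """Malformed line-listing content, annotated with the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(f"row {row}: {message}" if row is not None else message)


def format_reaction(r: Reaction) -> str:
    dur = "n/a" if r.duration_days is None else _format_number(r.duration_days)
    if r.seriousness_criteria:
        ser = ",".join(c.label for c in _CRITERIA_ORDER if c in r.seriousness_criteria)
    else:
        ser = "No"
    if ";" in r.pt:
        raise ValueError(f"PT {r.pt!r} contains ';', which the dialect reserves")
    return f"{r.pt} ({dur} - {r.outcome.label} - {ser})"


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_reaction(block: str) -> Reaction:
    """Parse one serialized reaction block back into a Reaction."""
    block = block.strip()
    if not block.endswith(")"):
        raise ValueError(f"reaction block {block!r} missing '(...)' suffix")
    cut = block.rfind(" (")
    if cut < 1:
        raise ValueError(f"reaction block {block!r} has no PT/detail separator")
    pt, inner = block[:cut], block[cut + 2 : -1]
    parts = inner.split(" - ")
    if len(parts) != 3:
        raise ValueError(f"reaction block {block!r}: expected 'duration - outcome - seriousness'")
    dur_s, out_s, ser_s = parts
    duration = None if dur_s.strip().lower() == "n/a" else float(dur_s)
    if duration is not None and duration < 0:
        raise ValueError(f"negative duration in {block!r}")
    outcome = Outcome.from_label(out_s)
    if ser_s.strip().lower() == "no":
        criteria: frozenset[SeriousnessCriterion] = frozenset()
    else:
        criteria = frozenset(
            SeriousnessCriterion.from_label(tok) for tok in ser_s.split(",")
        )
    return Reaction(pt=pt, outcome=outcome, seriousness_criteria=criteria,
                    duration_days=duration)


def _row_of(icsr: ICSR) -> list[str]:
    return [
        icsr.case_id,
        icsr.report_date.isoformat(),
        icsr.source_qualification.label,
        icsr.sex.label,
        icsr.age_group.label,
        icsr.region.short_label,
        "Yes" if icsr.from_literature else "No",
        ";".join(sorted(icsr.suspect_drugs)),
        ";".join(sorted(icsr.concomitant_drugs)),
        ";".join(format_reaction(r) for r in icsr.reactions),
    ]


def write_line_listing(collection: Iterable[ICSR], path: str | Path) -> None:
    """Write ICSRs as line-listing CSV; deterministic for a given collection."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(COLUMNS)
        for icsr in collection:
            w.writerow(_row_of(icsr))


def _parse_row(row: dict[str, str], rownum: int, strict: bool) -> ICSR:
    def enum_field(cls, value, fallback):
        try:
            return cls.from_label(value)
        except KeyError:
            if strict:
                raise LineListingError(f"unknown {cls.__name__} label {value!r}", rownum)
            logger.warning("row %d: unknown %s label %r -> %s",
                           rownum, cls.__name__, value, fallback.name)
            return fallback

    try:
        report_date = date.fromisoformat(row["report_date"])
    except ValueError as e:
        raise LineListingError(f"bad report_date: {e}", rownum)
    reactions_field = row["reactions"]
    if not reactions_field.strip():
        raise LineListingError("empty reactions field", rownum)
    try:
        reactions = tuple(parse_reaction(b) for b in reactions_field.split(";"))
    except (ValueError, KeyError) as e:
        raise LineListingError(f"malformed reaction block: {e}", rownum)
    suspects = [d for d in row["suspect_drugs"].split(";") if d.strip()]
    if not suspects:
        raise LineListingError("suspect_drugs must list at least one substance", rownum)
    concomitant = [d for d in row["concomitant_drugs"].split(";") if d.strip()]
    lit = row["from_literature"].strip().lower()
    if lit not in ("yes", "no"):
        raise LineListingError(f"from_literature must be Yes/No, got {row['from_literature']!r}", rownum)
    return ICSR(
        case_id=row["case_id"],
        report_date=report_date,
        source_qualification=enum_field(
            SourceQualification, row["source_qualification"],
            SourceQualification.NON_HEALTHCARE_PROFESSIONAL),
        sex=enum_field(Sex, row["sex"], Sex.UNKNOWN),
        age_group=enum_field(AgeGroup, row["age_group"], AgeGroup.NOT_SPECIFIED),
        region=enum_field(Region, row["region"], Region.NON_EEA),
        suspect_drugs=frozenset(suspects),
        concomitant_drugs=frozenset(concomitant),
        reactions=reactions,
        from_literature=(lit == "yes"),
    )


def read_line_listing(path: str | Path, strict: bool = False) -> list[ICSR]:
    """Read a line-listing CSV into a list of ICSRs.

    In strict mode any malformed row (bad reaction block, unknown enum
    label, duplicate case id, missing column) raises :class:`LineListingError`
    with the 1-based data-row number.  In lenient mode malformed rows are
    skipped with a logged warning and unknown enum labels degrade to
    Unknown/Not Specified.
    """
    path = Path(path)
    out: list[ICSR] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LineListingError("empty file (no header)")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise LineListingError(f"missing mandatory column(s): {', '.join(missing)}")
        for rownum, row in enumerate(reader, start=1):
            try:
                icsr = _parse_row(row, rownum, strict)
                if icsr.case_id in seen:
                    raise LineListingError(f"duplicate case_id {icsr.case_id!r}", rownum)
            except LineListingError as e:
                if strict:
                    raise
                logger.warning("skipping line-listing row: %s", e)
                continue
            seen.add(icsr.case_id)
            out.append(icsr)
    return out


def read_meddra_map(path: str | Path) -> MeddraMap:
    """Read a PT->SOC TSV (header ``pt<TAB>soc``)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pt", "soc"]:
            raise ValueError(f"{path}: expected header 'pt\\tsoc', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
            pt, soc = parts[0], parts[1]
            prev = mapping.get(pt)
            if prev is not None and prev != soc:
                raise ValueError(
                    f"{path}:{lineno}: PT {pt!r} mapped to two SOCs ({prev!r}, {soc!r})")
            mapping[pt] = soc
    return MeddraMap(mapping, version_label=path.stem)


def write_meddra_map(mapping: MeddraMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("pt\tsoc\n")
        for pt, soc in sorted(mapping.items()):
            fh.write(f"{pt}\t{soc}\n")


def read_expected_terms(path: str | Path) -> ExpectedTerms:
    """Read an expected-terms file: one PT per line, '#' comments allowed."""
    terms: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
    return ExpectedTerms(terms)


def write_expected_terms(terms: Sequence[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("# expected adverse reactions (one preferred term per line)\n")
        for t in sorted(terms):
            fh.write(t + "\n")
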