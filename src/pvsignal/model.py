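"""Domain types for individual case safety reports (ICSRs).

An ICSR is one spontaneous report of one patient's suspected adverse drug
reaction(s); each report carries one or more coded reactions (MedDRA
Preferred Terms) together with outcome and regulatory seriousness flags.
The enumerations below mirror the categories exposed by public
EudraVigilance-style line listings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Outcome",
    "SeriousnessCriterion",
    "SourceQualification",
    "Sex",
    "AgeGroup",
    "Region",
    "Reaction",
    "ICSR",
    "MeddraMap",
    "ExpectedTerms",
    "UNMAPPED_SOC",
    "norm_term",
    "norm_drug",
]

UNMAPPED_SOC = "Unmapped"


def norm_term(s: str) -> str:
    """Case-fold and collapse internal whitespace, for term comparison."""
    return " ".join(s.split()).casefold()


def norm_drug(s: str) -> str:
    """Normalize an active-substance name: trim, collapse spaces, lowercase."""
    return " ".join(s.split()).lower()


class _LabelledEnum(Enum):
    """Enum whose members carry the verbatim line-listing label."""

    def __init__(self, label: str):
        self.label = label

    @classmethod
    def from_label(cls, label: str):
        """Resolve a label case-insensitively; KeyError for unknown labels."""
        key = norm_term(label)
        try:
            return cls._label_index()[key]
        except KeyError:
            raise KeyError(f"{cls.__name__}: unknown label {label!r}") from None

    @classmethod
    def _label_index(cls):
        cached = cls.__dict__.get("_label_cache")
        if cached is None:
            cached = {norm_term(m.label): m for m in cls}
            setattr(cls, "_label_cache", cached)
        return cached


class Outcome(_LabelledEnum):
    """Reaction outcome, in the standard spontaneous-reporting terminology."""

    RECOVERED_RESOLVED = "Recovered/resolved"
    RECOVERING_RESOLVING = "Recovering/resolving"
    RECOVERED_WITH_SEQUELAE = "Recovered/resolved with sequelae"
    NOT_RECOVERED = "Not recovered/not resolved"
    FATAL = "Fatal"
    UNKNOWN = "Unknown"


class SeriousnessCriterion(_LabelledEnum):
    """Regulatory flags that make a reaction 'serious'."""

    DEATH = "Death"
    LIFE_THREATENING = "Life Threatening"
    HOSPITALIZATION = "Caused/Prolonged Hospitalisation"
    DISABILITY = "Disabling"
    CONGENITAL_ANOMALY = "Congenital Anomaly"
    OTHER_MEDICALLY_IMPORTANT = "Other Medically Important Condition"


class SourceQualification(_LabelledEnum):
    HEALTHCARE_PROFESSIONAL = "Healthcare Professional"
    NON_HEALTHCARE_PROFESSIONAL = "Non-Healthcare Professional"


class Sex(_LabelledEnum):
    MALE = "Male"
    FEMALE = "Female"
    UNKNOWN = "Unknown"


class AgeGroup(_LabelledEnum):
    """EudraVigilance public-portal age buckets."""

    M_0_1 = "0-1 Month"
    M2_Y2 = "2 Months-2 Years"
    Y3_11 = "3-11 Years"
    Y12_17 = "12-17 Years"
    Y18_64 = "18-64 Years"
    Y65_85 = "65-85 Years"
    Y85_PLUS = "More than 85 Years"
    NOT_SPECIFIED = "Not Specified"


class Region(_LabelledEnum):
    EEA = "European Economic Area"
    NON_EEA = "Non-European Economic Area"

    # line-listing short labels
    @classmethod
    def from_label(cls, label: str):
        key = norm_term(label)
        if key == "eea":
            return cls.EEA
        if key == "non-eea":
            return cls.NON_EEA
        return super().from_label(label)

    @property
    def short_label(self) -> str:
        return "EEA" if self is Region.EEA else "Non-EEA"


@dataclass(frozen=True)
class Reaction:
    """One suspected adverse reaction inside an ICSR.

    ``serious`` is derived: a reaction is serious exactly when at least one
    regulatory seriousness criterion is attached.
    """

    pt: str
    outcome: Outcome
    seriousness_criteria: frozenset[SeriousnessCriterion] = frozenset()
    duration_days: float | None = None

    def __post_init__(self):
        if not self.pt.strip():
            raise ValueError("Reaction PT must be nonempty")
        object.__setattr__(self, "pt", " ".join(self.pt.split()))
        object.__setattr__(
            self, "seriousness_criteria", frozenset(self.seriousness_criteria)
        )
        if self.duration_days is not None and self.duration_days < 0:
            raise ValueError(f"negative duration_days for PT {self.pt!r}")

    @property
    def serious(self) -> bool:
        return bool(self.seriousness_criteria)


@dataclass(frozen=True)
class ICSR:
    """One individual case safety report."""

    case_id: str
    report_date: date
    source_qualification: SourceQualification
    sex: Sex
    age_group: AgeGroup
    region: Region
    suspect_drugs: frozenset[str]
    reactions: tuple[Reaction, ...]
    concomitant_drugs: frozenset[str] = frozenset()
    from_literature: bool = False

    def __post_init__(self):
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        object.__setattr__(
            self, "suspect_drugs", frozenset(norm_drug(d) for d in self.suspect_drugs)
        )
        object.__setattr__(
            self,
            "concomitant_drugs",
            frozenset(norm_drug(d) for d in self.concomitant_drugs),
        )
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if not self.suspect_drugs:
            raise ValueError(f"{self.case_id}: suspect_drugs must be nonempty")
        if not self.reactions:
            raise ValueError(f"{self.case_id}: at least one reaction is required")

    @property
    def has_vaccine_suspect(self) -> bool:
        """True when any suspect drug names a vaccine.

        The line-listing dialect carries no dedicated flag; vaccine
        involvement is recognised from the substance name itself.
        """
        return any("vaccine" in d for d in self.suspect_drugs)

    @property
    def serious(self) -> bool:
        """Case-level seriousness: any reaction serious."""
        return any(r.serious for r in self.reactions)

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(r.pt for r in self.reactions)


class MeddraMap:
    """PT -> primary SOC lookup (single assignment).

    Lookups are whitespace/case-insensitive.  PTs absent from the map
    resolve to the sentinel SOC ``"Unmapped"`` with a one-time warning so
    that denominators are never silently changed by dictionary gaps.
    """

    def __init__(self, pt_to_soc: Mapping[str, str], version_label: str = ""):
        self.version_label = version_label
        self._map: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for pt, soc in pt_to_soc.items():
            key = norm_term(pt)
            if key in self._map and self._map[key] != soc:
                raise ValueError(
                    f"PT {pt!r} mapped to two SOCs: {self._map[key]!r} and {soc!r}"
                )
            self._map[key] = soc
            self._display[key] = " ".join(pt.split())
        self._warned: set[str] = set()

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return norm_term(pt) in self._map

    def soc_of(self, pt: str) -> str:
        key = norm_term(pt)
        soc = self._map.get(key)
        if soc is None:
            if key not in self._warned:
                self._warned.add(key)
                logger.warning("PT %r not in MedDRA map; using sentinel SOC %r",
                               pt, UNMAPPED_SOC)
            return UNMAPPED_SOC
        return soc

    def items(self):
        """(display PT, SOC) pairs in insertion order."""
        return [(self._display[k], s) for k, s in self._map.items()]


class ExpectedTerms:
    """PTs listed in the index drug's summary of product characteristics."""

    def __init__(self, terms: Iterable[str]):
        self._terms = frozenset(norm_term(t) for t in terms if t.strip())

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, pt: str) -> bool:
        return norm_term(pt) in self._terms
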