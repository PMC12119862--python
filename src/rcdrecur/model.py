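"""Domain types and coded-vocabulary primitives.

Everything downstream — cohort selection, the recurrence engine, the
validation metrics and the synthetic generator — speaks in terms of the
types defined here: dated coded events from the routinely collected data
(RCD) sources, tumour registrations, death records, and the seven-category
clinical outcome taxonomy with its priority order.

Code membership is by longest-prefix match on normalised codes (dots
stripped, upper-cased), which absorbs the dialect differences between
hospital-episode and registry coding ("C50.4" vs "C504").
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "OutcomeType",
    "RECURRENCE_TYPES",
    "DEFAULT_PRIORITY",
    "PriorityOrder",
    "Source",
    "CodingSystem",
    "Laterality",
    "Intent",
    "Behaviour",
    "CodedEvent",
    "TumourRegistration",
    "DeathRecord",
    "PatientHistory",
    "OutcomeEvent",
    "CodeSet",
    "CodeRole",
    "CodeConfig",
    "normalize_code",
    "code_matches",
    "classify_diagnosis_code",
]


class OutcomeType(enum.Enum):
    """The seven-category clinical outcome taxonomy.

    Locoregional recurrence is a return of disease in the ipsilateral
    breast and/or regional lymph nodes; distant recurrence is metastasis
    elsewhere in the body not present at primary diagnosis; contralateral
    breast cancer is a new invasive primary in the opposite breast.
    Unknown-type covers evidence of recurrence without a resolvable site.
    """

    LOCOREGIONAL_RECURRENCE = "LOCOREGIONAL_RECURRENCE"
    DISTANT_RECURRENCE = "DISTANT_RECURRENCE"
    RECURRENCE_TYPE_UNKNOWN = "RECURRENCE_TYPE_UNKNOWN"
    CONTRALATERAL_BREAST_CANCER = "CONTRALATERAL_BREAST_CANCER"
    BREAST_CANCER_DEATH = "BREAST_CANCER_DEATH"
    NON_BREAST_MALIGNANCY = "NON_BREAST_MALIGNANCY"
    NON_BREAST_CANCER_DEATH = "NON_BREAST_CANCER_DEATH"


RECURRENCE_TYPES = frozenset(
    {
        OutcomeType.LOCOREGIONAL_RECURRENCE,
        OutcomeType.DISTANT_RECURRENCE,
        OutcomeType.RECURRENCE_TYPE_UNKNOWN,
        OutcomeType.CONTRALATERAL_BREAST_CANCER,
    }
)

#: Default same-date priority, most informative first.  The only hard
#: constraint from the clinical rationale is that distant recurrence
#: outranks locoregional (a same-day liver metastasis and ipsilateral
#: recurrence is recorded as distant); the remainder orders outcomes by
#: clinical informativeness and is overridable in configuration.
DEFAULT_PRIORITY: tuple[OutcomeType, ...] = (
    OutcomeType.DISTANT_RECURRENCE,
    OutcomeType.LOCOREGIONAL_RECURRENCE,
    OutcomeType.RECURRENCE_TYPE_UNKNOWN,
    OutcomeType.CONTRALATERAL_BREAST_CANCER,
    OutcomeType.BREAST_CANCER_DEATH,
    OutcomeType.NON_BREAST_MALIGNANCY,
    OutcomeType.NON_BREAST_CANCER_DEATH,
)


class PriorityOrder:
    """A total order over the seven outcome labels (lower rank wins)."""

    def __init__(self, order: Sequence[OutcomeType] = DEFAULT_PRIORITY):
        order = tuple(order)
        if sorted(o.value for o in order) != sorted(o.value for o in OutcomeType):
            raise ValueError("priority order must be a permutation of the 7 outcome labels")
        if order.index(OutcomeType.DISTANT_RECURRENCE) >= order.index(
            OutcomeType.LOCOREGIONAL_RECURRENCE
        ):
            raise ValueError("distant recurrence must outrank locoregional recurrence")
        self._rank = {o: i for i, o in enumerate(order)}
        self.order = order

    def rank(self, outcome: OutcomeType) -> int:
        return self._rank[outcome]

    def best(self, outcomes: Iterable[OutcomeType]) -> OutcomeType:
        return min(outcomes, key=self.rank)


class Source(enum.Enum):
    COSD = "COSD"  # national cancer registration dataset
    HES = "HES"  # hospital episode statistics
    RTDS = "RTDS"  # radiotherapy dataset
    DIDS = "DIDS"  # diagnostic imaging dataset
    CWT = "CWT"  # cancer waiting times
    SACT = "SACT"  # systemic anti-cancer therapy


#: Evidence-labelling precedence when identical dates arrive from several
#: sources (the outcome itself is unaffected — dates are equal).
SOURCE_ORDER: tuple[Source, ...] = (
    Source.COSD,
    Source.HES,
    Source.CWT,
    Source.SACT,
    Source.RTDS,
    Source.DIDS,
)


class CodingSystem(enum.Enum):
    ICD10 = "ICD10"
    ICD9 = "ICD9"
    OPCS4 = "OPCS4"
    MODALITY = "MODALITY"  # imaging modality labels (DIDS)
    TREATMENT = "TREATMENT"  # therapy event labels (CWT/SACT/RTDS/COSD)


#: Which coding systems each source may legitimately carry.
_SOURCE_SYSTEMS: dict[Source, frozenset[CodingSystem]] = {
    Source.COSD: frozenset({CodingSystem.ICD10, CodingSystem.ICD9, CodingSystem.OPCS4, CodingSystem.TREATMENT}),
    Source.HES: frozenset({CodingSystem.ICD10, CodingSystem.ICD9, CodingSystem.OPCS4}),
    Source.RTDS: frozenset({CodingSystem.TREATMENT}),
    Source.DIDS: frozenset({CodingSystem.MODALITY}),
    Source.CWT: frozenset({CodingSystem.TREATMENT}),
    Source.SACT: frozenset({CodingSystem.TREATMENT}),
}


class Laterality(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BILATERAL = "BILATERAL"
    UNKNOWN = "UNKNOWN"


def opposite_laterality(lat: Laterality) -> Optional[Laterality]:
    if lat is Laterality.LEFT:
        return Laterality.RIGHT
    if lat is Laterality.RIGHT:
        return Laterality.LEFT
    return None


class Intent(enum.Enum):
    CURATIVE = "CURATIVE"
    PALLIATIVE = "PALLIATIVE"
    UNKNOWN = "UNKNOWN"


class Behaviour(enum.Enum):
    INVASIVE = "INVASIVE"
    IN_SITU = "IN_SITU"
    OTHER = "OTHER"


_CODE_RE = re.compile(r"^[A-Z0-9]+$")


def normalize_code(code: str) -> str:
    """Strip dots and whitespace, upper-case.

    Raises ``ValueError`` if the result is empty or non-alphanumeric.
    """
    norm = code.replace(".", "").replace(" ", "").upper()
    if not norm or not _CODE_RE.match(norm):
        raise ValueError(f"malformed code: {code!r}")
    return norm


@dataclass(frozen=True)
class CodeSet:
    """A named set of code prefixes; membership is by prefix match."""

    name: str
    prefixes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "prefixes", frozenset(normalize_code(p) for p in self.prefixes)
        )

    def __contains__(self, code: str) -> bool:
        return code_matches(code, self)


def code_matches(code: str, codeset: CodeSet) -> bool:
    """True iff the normalised code starts with any prefix in the set."""
    norm = normalize_code(code)
    return any(norm.startswith(p) for p in codeset.prefixes)


@dataclass(frozen=True)
class CodedEvent:
    """One dated coded record from one RCD source — the engine's atom."""

    patient_id: str
    source: Source
    date: Date
    system: CodingSystem
    code: str
    laterality: Laterality = Laterality.UNKNOWN
    intent: Intent = Intent.UNKNOWN
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.system not in _SOURCE_SYSTEMS[self.source]:
            raise ValueError(
                f"coding system {self.system.value} is not valid for source {self.source.value}"
            )


@dataclass(frozen=True)
class TumourRegistration:
    tumour_id: str
    patient_id: str
    diagnosis_date: Date
    site_code: str
    behaviour: Behaviour = Behaviour.INVASIVE
    laterality: Laterality = Laterality.UNKNOWN
    provisional: bool = False


@dataclass(frozen=True)
class DeathRecord:
    patient_id: str
    death_date: Date
    underlying_cause: str
    mentioned_causes: tuple[str, ...] = ()


@dataclass
class PatientHistory:
    """All registrations, coded events and death information for one woman."""

    patient_id: str
    index_registration: TumourRegistration
    other_registrations: list[TumourRegistration] = field(default_factory=list)
    events: list[CodedEvent] = field(default_factory=list)
    death: Optional[DeathRecord] = None
    emigration_date: Optional[Date] = None

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.date, SOURCE_ORDER.index(e.source), e.code))
        if self.death is not None:
            kept = [e for e in self.events if e.date <= self.death.death_date]
            if len(kept) < len(self.events):
                import logging

                logging.getLogger(__name__).warning(
                    "patient %s: discarded %d event(s) dated after death",
                    self.patient_id,
                    len(self.events) - len(kept),
                )
            self.events = kept

    @property
    def index_date(self) -> Date:
        return self.index_registration.diagnosis_date


@dataclass(frozen=True)
class OutcomeEvent:
    """A dated, typed clinical outcome — the currency of both the engine
    output and the gold-standard follow-up."""

    patient_id: str
    date: Date
    outcome: OutcomeType


class CodeRole(enum.Enum):
    BREAST_PRIMARY = "BREAST_PRIMARY"
    REGIONAL_NODE_SECONDARY = "REGIONAL_NODE_SECONDARY"
    DISTANT_SECONDARY = "DISTANT_SECONDARY"
    OTHER_MALIGNANCY = "OTHER_MALIGNANCY"
    IGNORED_NMSC = "IGNORED_NMSC"
    NON_MALIGNANT = "NON_MALIGNANT"


def _default_codesets() -> dict[CodeRole, CodeSet]:
    return {
        CodeRole.BREAST_PRIMARY: CodeSet("breast_primary", frozenset({"C50", "174"})),
        CodeRole.REGIONAL_NODE_SECONDARY: CodeSet("regional_node_secondary", frozenset({"C77"})),
        CodeRole.DISTANT_SECONDARY: CodeSet("distant_secondary", frozenset({"C78", "C79"})),
        CodeRole.IGNORED_NMSC: CodeSet("ignored_nmsc", frozenset({"C44", "173"})),
    }


# ICD-9 invasive malignancy chapter: 140–208.
_ICD9_MALIGNANT = re.compile(r"^(1[4-9]\d|20[0-8])")
# ICD-10 malignancy chapter: C00–C97.
_ICD10_MALIGNANT = re.compile(r"^C(\d\d)")


class CodeConfig:
    """Holds the configurable code lists and checks them for overlap.

    The exact published lists live outside the main text; the defaults
    here follow standard ICD semantics (breast primary C50/174, regional
    nodes C77, distant secondaries C78–C79, ignored non-melanoma skin
    C44/173) and every set is replaceable.
    """

    def __init__(self, codesets: Optional[Mapping[CodeRole, CodeSet]] = None):
        sets = _default_codesets()
        if codesets:
            sets.update(codesets)
        # overlap is a configuration error, caught at load time
        roles = [r for r in sets if sets[r].prefixes]
        for i, a in enumerate(roles):
            for b in roles[i + 1 :]:
                for pa in sets[a].prefixes:
                    for pb in sets[b].prefixes:
                        if pa.startswith(pb) or pb.startswith(pa):
                            raise ValueError(
                                f"code sets {a.value} and {b.value} overlap on "
                                f"prefixes {pa!r} / {pb!r}"
                            )
        self._sets = sets

    def codeset(self, role: CodeRole) -> CodeSet:
        return self._sets.get(role, CodeSet(role.value))


def classify_diagnosis_code(code: str, config: Optional[CodeConfig] = None) -> CodeRole:
    """Assign a diagnosis code to exactly one role.

    Roles are checked in a fixed order — the named sets first (non-melanoma
    skin before the generic malignancy fallback), then any other invasive
    malignancy-chapter code maps to OTHER_MALIGNANCY, and everything else
    is NON_MALIGNANT.  Pure and total over well-formed codes.
    """
    config = config or CodeConfig()
    norm = normalize_code(code)
    for role in (
        CodeRole.BREAST_PRIMARY,
        CodeRole.REGIONAL_NODE_SECONDARY,
        CodeRole.DISTANT_SECONDARY,
        CodeRole.IGNORED_NMSC,
    ):
        if code_matches(norm, config.codeset(role)):
            return role
    if _ICD10_MALIGNANT.match(norm) or _ICD9_MALIGNANT.match(norm):
        return CodeRole.OTHER_MALIGNANCY
    return CodeRole.NON_MALIGNANT
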