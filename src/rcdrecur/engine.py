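"""The deterministic recurrence-identification algorithm.

The engine turns one woman's coded history into dated outcome events in
four stages:

1. *Candidate extraction* — independent rule families scan registrations,
   diagnosis codes, procedures, therapy events and the death record, each
   emitting :class:`CandidateOutcome` objects with an evidence chain.
2. *Filters* — two rule families learned during further training remove
   known false-positive patterns: reconstructive/oncoplastic surgery
   masquerading as locoregional or contralateral recurrence, and regular
   single-day infusion schedules (bisphosphonate protocols) masquerading
   as palliative chemotherapy.
3. *Optional post-validation adjustment* — locoregional, unknown-type and
   contralateral events within the first year after diagnosis are
   ignored (that period is dominated by reconstructive surgery noise).
4. *Same-date resolution* — when several outcomes fall on one date the
   one of highest priority survives (distant metastasis outranks a
   same-day ipsilateral recurrence), with the evidence lists merged.

Everything is pure and deterministic: identical history and configuration
give identical output regardless of input record order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Iterable, Optional, Sequence

from .cohort import ONE_YEAR_DAYS, THREE_MONTHS_DAYS, FollowUpWindow
from .model import (
    CodeConfig,
    CodeRole,
    CodedEvent,
    CodingSystem,
    CodeSet,
    DEFAULT_PRIORITY,
    Laterality,
    OutcomeType,
    PatientHistory,
    PriorityOrder,
    Source,
    SOURCE_ORDER,
    TumourRegistration,
    classify_diagnosis_code,
    code_matches,
    normalize_code,
    opposite_laterality,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateOutcome",
    "EngineConfig",
    "AlgorithmResult",
    "candidates_from_registrations",
    "candidates_from_diagnosis_codes",
    "candidates_from_procedures",
    "candidates_from_therapy",
    "candidates_from_death",
    "reconstruction_filter",
    "infusion_filter",
    "resolve_same_date",
    "apply_post_validation_adjustment",
    "run_algorithm",
]

#: Therapy-event code labels used in TREATMENT-system coded events.
CHEMOTHERAPY = "CHEMOTHERAPY"
RADIOTHERAPY = "RADIOTHERAPY"

#: Conflicting-site evidence window for the unknown-type rule (days).
UNKNOWN_TYPE_SITE_WINDOW = 14


@dataclass(frozen=True)
class CandidateOutcome:
    """A dated candidate outcome with its triggering evidence.

    ``date`` always equals the earliest evidence date; ``rule_id`` names
    the generating rule so every emitted event is auditable.
    """

    patient_id: str
    date: Date
    outcome: OutcomeType
    evidence: tuple = ()
    rule_id: str = ""

    def __post_init__(self):
        if not self.evidence:
            raise ValueError("candidate outcome requires non-empty evidence")
        earliest = min(_evidence_date(e) for e in self.evidence)
        if self.date != earliest:
            raise ValueError("candidate date must equal earliest evidence date")


def _evidence_date(ev) -> Date:
    if isinstance(ev, CodedEvent):
        return ev.date
    if isinstance(ev, TumourRegistration):
        return ev.diagnosis_date
    return ev.death_date  # DeathRecord


def _default_reconstruction_codes() -> CodeSet:
    # OPCS chapter B: B29 reconstruction of breast, B30/B31 other and
    # plastic operations on breast (symmetrising / oncoplastic work).
    return CodeSet("reconstruction", frozenset({"B29", "B30", "B31"}))


def _default_resection_codes() -> CodeSet:
    # B27 total excision of breast (mastectomy), B28 partial excision.
    return CodeSet("breast_resection", frozenset({"B27", "B28"}))


def _default_palliative_care_codes() -> CodeSet:
    return CodeSet("palliative_care", frozenset({"Z515"}))


@dataclass
class EngineConfig:
    """Tunable rule constants for the engine.

    ``primary_treatment_window_days`` is the period after diagnosis during
    which surgery/systemic/radiotherapy events are primary treatment, not
    recurrence evidence.  The infusion-filter parameters bracket the
    intravenous bisphosphonate protocol (monthly infusions moving to
    3–6-monthly over five years).
    """

    codes: CodeConfig = field(default_factory=CodeConfig)
    primary_treatment_window_days: int = 270
    reconstruction_codes: CodeSet = field(default_factory=_default_reconstruction_codes)
    resection_codes: CodeSet = field(default_factory=_default_resection_codes)
    palliative_care_codes: CodeSet = field(default_factory=_default_palliative_care_codes)
    infusion_min_count: int = 4
    infusion_min_gap_days: int = 21
    infusion_max_gap_days: int = 200
    adjustment_flag: bool = False
    priority: PriorityOrder = field(default_factory=PriorityOrder)
    reconstruction_filter_enabled: bool = True
    infusion_filter_enabled: bool = True

    def __post_init__(self):
        if self.infusion_min_gap_days >= self.infusion_max_gap_days:
            raise ValueError("infusion_min_gap_days must be < infusion_max_gap_days")
        if self.primary_treatment_window_days <= 0 or self.infusion_min_gap_days <= 0:
            raise ValueError("all windows must be positive")

    def codeset(self, role: CodeRole) -> CodeSet:
        return self.codes.codeset(role)


# ---------------------------------------------------------------------------
# candidate extraction


def candidates_from_registrations(
    history: PatientHistory, config: EngineConfig
) -> list[CandidateOutcome]:
    """Outcomes evidenced by new tumour registrations.

    A non-provisional invasive breast registration of opposite laterality
    more than three months after the index diagnosis is a contralateral
    breast cancer (earlier ones are synchronous-bilateral material and
    excluded upstream).  Same- or unknown-laterality breast
    re-registrations are locoregional recurrences; any other invasive
    non-breast registration (non-melanoma skin excepted) is a non-breast
    malignancy.
    """
    out: list[CandidateOutcome] = []
    index = history.index_registration
    idx_date = index.diagnosis_date
    opp = opposite_laterality(index.laterality)
    for reg in sorted(history.other_registrations, key=lambda r: (r.diagnosis_date, r.tumour_id)):
        if reg.diagnosis_date <= idx_date or reg.behaviour.value != "INVASIVE":
            continue
        try:
            role = classify_diagnosis_code(reg.site_code, config.codes)
        except ValueError:
            continue
        if role is CodeRole.BREAST_PRIMARY:
            if reg.provisional:
                continue
            offset = (reg.diagnosis_date - idx_date).days
            if opp is not None and reg.laterality is opp:
                if offset > THREE_MONTHS_DAYS:
                    out.append(
                        CandidateOutcome(
                            history.patient_id,
                            reg.diagnosis_date,
                            OutcomeType.CONTRALATERAL_BREAST_CANCER,
                            (reg,),
                            "registration.contralateral",
                        )
                    )
                # within 3 months: synchronous bilateral, handled upstream
            else:
                out.append(
                    CandidateOutcome(
                        history.patient_id,
                        reg.diagnosis_date,
                        OutcomeType.LOCOREGIONAL_RECURRENCE,
                        (reg,),
                        "registration.ipsilateral_reregistration",
                    )
                )
        elif role in (CodeRole.OTHER_MALIGNANCY,):
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    reg.diagnosis_date,
                    OutcomeType.NON_BREAST_MALIGNANCY,
                    (reg,),
                    "registration.non_breast_malignancy",
                )
            )
        # regional/distant secondary registrations feed the diagnosis-code
        # rules via coded events; NMSC and non-malignant codes are ignored
    return out


def _diagnosis_events(history: PatientHistory) -> list[CodedEvent]:
    return [
        e
        for e in history.events
        if e.system in (CodingSystem.ICD10, CodingSystem.ICD9)
        and e.source in (Source.HES, Source.COSD)
    ]


def candidates_from_diagnosis_codes(
    history: PatientHistory, config: EngineConfig
) -> list[CandidateOutcome]:
    """Outcomes evidenced by hospital/registry diagnosis codes.

    Secondary-malignancy codes inside the primary-treatment window are
    metastases already present at diagnosis, not recurrences, and are
    ignored.  After the window, the first distant-secondary code is a
    distant recurrence and a regional-node secondary is locoregional.
    A palliative-care code with no site-specific secondary code within
    ±14 days indicates recurrence of unknown type.
    """
    out: list[CandidateOutcome] = []
    idx_date = history.index_date
    window_end = idx_date + timedelta(days=config.primary_treatment_window_days)
    events = _diagnosis_events(history)

    distant_done = False
    regional_done = False
    for ev in events:
        try:
            role = classify_diagnosis_code(ev.code, config.codes)
        except ValueError:
            continue
        if ev.date < window_end:
            continue
        if role is CodeRole.DISTANT_SECONDARY and not distant_done:
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    ev.date,
                    OutcomeType.DISTANT_RECURRENCE,
                    (ev,),
                    "diagnosis.distant_secondary",
                )
            )
            distant_done = True
        elif role is CodeRole.REGIONAL_NODE_SECONDARY and not regional_done:
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    ev.date,
                    OutcomeType.LOCOREGIONAL_RECURRENCE,
                    (ev,),
                    "diagnosis.regional_node_secondary",
                )
            )
            regional_done = True

    # unknown-type rule: palliative-care coding without a site
    site_dates = [
        e.date
        for e in events
        if _safe_role(e.code, config) in (CodeRole.DISTANT_SECONDARY, CodeRole.REGIONAL_NODE_SECONDARY)
    ]
    for ev in events:
        if not code_matches(ev.code, config.palliative_care_codes):
            continue
        if ev.date < window_end:
            continue
        if any(abs((ev.date - d).days) <= UNKNOWN_TYPE_SITE_WINDOW for d in site_dates):
            continue
        out.append(
            CandidateOutcome(
                history.patient_id,
                ev.date,
                OutcomeType.RECURRENCE_TYPE_UNKNOWN,
                (ev,),
                "diagnosis.palliative_care_no_site",
            )
        )
        break  # first such event only
    return out


def _safe_role(code: str, config: EngineConfig) -> CodeRole:
    try:
        return classify_diagnosis_code(code, config.codes)
    except ValueError:
        return CodeRole.NON_MALIGNANT


def _procedure_events(history: PatientHistory) -> list[CodedEvent]:
    return [e for e in history.events if e.system is CodingSystem.OPCS4]


def candidates_from_procedures(
    history: PatientHistory, config: EngineConfig
) -> list[CandidateOutcome]:
    """Outcomes evidenced by breast-resection procedures.

    The first resection at or after the index diagnosis is the primary
    cancer surgery; resections more than the primary-treatment window
    after it indicate recurrence (ipsilateral → locoregional, opposite
    side → contralateral).  Candidates keep their procedure event as
    evidence so the reconstruction filter can vet them.
    """
    out: list[CandidateOutcome] = []
    idx_date = history.index_date
    procs = [
        e
        for e in _procedure_events(history)
        if e.date >= idx_date
        and (
            code_matches(e.code, config.resection_codes)
            or code_matches(e.code, config.reconstruction_codes)
        )
    ]
    resections = [e for e in procs if code_matches(e.code, config.resection_codes)]
    if resections:
        primary_date = resections[0].date
    else:
        primary_date = idx_date
        if procs:
            logger.info(
                "patient %s: no primary breast surgery found; using index date as anchor",
                history.patient_id,
            )
    window_end = primary_date + timedelta(days=config.primary_treatment_window_days)
    index_side = history.index_registration.laterality
    opp = opposite_laterality(index_side)
    for ev in procs:
        if ev.date <= window_end:
            continue
        if opp is not None and ev.laterality is opp:
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    ev.date,
                    OutcomeType.CONTRALATERAL_BREAST_CANCER,
                    (ev,),
                    "procedure.contralateral_resection",
                )
            )
        else:
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    ev.date,
                    OutcomeType.LOCOREGIONAL_RECURRENCE,
                    (ev,),
                    "procedure.ipsilateral_resection",
                )
            )
    return out


def _therapy_events(history: PatientHistory) -> list[CodedEvent]:
    return [e for e in history.events if e.system is CodingSystem.TREATMENT]


def _chemo_blocks(events: Sequence[CodedEvent], block_gap_days: int = 90) -> list[list[CodedEvent]]:
    """Group chemotherapy attendances into treatment blocks; a gap larger
    than ``block_gap_days`` starts a new block."""
    blocks: list[list[CodedEvent]] = []
    for ev in events:
        if blocks and (ev.date - blocks[-1][-1].date).days <= block_gap_days:
            blocks[-1].append(ev)
        else:
            blocks.append([ev])
    return blocks


def candidates_from_therapy(
    history: PatientHistory, config: EngineConfig
) -> list[CandidateOutcome]:
    """Outcomes evidenced by therapy events.

    Palliative systemic therapy indicates distant recurrence, as does a
    chemotherapy block starting long after the adjuvant block (and as
    does palliative radiotherapy to a non-breast site).  Repeat breast
    radiotherapy more than a year after diagnosis indicates locoregional
    recurrence.  These are deliberately eager rules; the infusion filter
    downstream removes regular bisphosphonate-style schedules.
    """
    out: list[CandidateOutcome] = []
    idx_date = history.index_date
    window = timedelta(days=config.primary_treatment_window_days)
    therapy = _therapy_events(history)

    chemo = [e for e in therapy if normalize_code(e.code) == CHEMOTHERAPY]
    palliative_chemo = [e for e in chemo if e.intent.value == "PALLIATIVE"]
    for ev in palliative_chemo[:1]:
        out.append(
            CandidateOutcome(
                history.patient_id,
                ev.date,
                OutcomeType.DISTANT_RECURRENCE,
                (ev,),
                "therapy.palliative_systemic",
            )
        )

    # late chemotherapy blocks: anything starting more than the primary-
    # treatment window after the end of the adjuvant block (the block
    # starting within the window of diagnosis)
    blocks = _chemo_blocks(chemo)
    adjuvant_end: Optional[Date] = None
    for block in blocks:
        start = block[0].date
        if adjuvant_end is None and start < idx_date + window:
            adjuvant_end = block[-1].date
            continue
        anchor = adjuvant_end if adjuvant_end is not None else idx_date
        if (start - anchor).days > config.primary_treatment_window_days:
            if any(e.intent.value == "PALLIATIVE" for e in block):
                continue  # already emitted by the palliative rule
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    start,
                    OutcomeType.DISTANT_RECURRENCE,
                    tuple(block),
                    "therapy.late_chemotherapy_block",
                )
            )

    radio = [e for e in therapy if normalize_code(e.code) == RADIOTHERAPY]
    for ev in radio:
        site = (ev.attributes.get("site") or "").lower()
        if ev.intent.value == "PALLIATIVE" and site not in ("", "breast"):
            out.append(
                CandidateOutcome(
                    history.patient_id,
                    ev.date,
                    OutcomeType.DISTANT_RECURRENCE,
                    (ev,),
                    "therapy.palliative_radiotherapy_non_breast",
                )
            )
            break
    breast_rt = [e for e in radio if (e.attributes.get("site") or "breast").lower() == "breast"]
    if breast_rt:
        first_rt = breast_rt[0]
        for ev in breast_rt[1:]:
            if (ev.date - idx_date).days > ONE_YEAR_DAYS and (
                ev.date - first_rt.date
            ).days > config.primary_treatment_window_days:
                out.append(
                    CandidateOutcome(
                        history.patient_id,
                        ev.date,
                        OutcomeType.LOCOREGIONAL_RECURRENCE,
                        (ev,),
                        "therapy.repeat_breast_radiotherapy",
                    )
                )
                break
    return out


def candidates_from_death(
    history: PatientHistory, config: EngineConfig
) -> list[CandidateOutcome]:
    """Death mapped by underlying cause: breast codes → breast-cancer
    death, anything else → non-breast-cancer death."""
    if history.death is None:
        return []
    death = history.death
    try:
        role = classify_diagnosis_code(death.underlying_cause, config.codes)
    except ValueError:
        role = CodeRole.NON_MALIGNANT
    outcome = (
        OutcomeType.BREAST_CANCER_DEATH
        if role in (CodeRole.BREAST_PRIMARY, CodeRole.DISTANT_SECONDARY)
        else OutcomeType.NON_BREAST_CANCER_DEATH
    )
    return [
        CandidateOutcome(
            history.patient_id, death.death_date, outcome, (death,), "death.underlying_cause"
        )
    ]


# ---------------------------------------------------------------------------
# filters


def reconstruction_filter(
    candidates: Sequence[CandidateOutcome],
    history: PatientHistory,
    config: EngineConfig,
) -> list[CandidateOutcome]:
    """Drop surgical locoregional/contralateral candidates that look like
    reconstructive or oncoplastic work.

    A candidate is removed when its evidence procedure carries a
    reconstruction code, or when no malignancy diagnosis code (breast
    primary or secondary) is recorded within ±91 days of the procedure.
    """
    malignancy_dates = [
        e.date
        for e in _diagnosis_events(history)
        if _safe_role(e.code, config)
        in (CodeRole.BREAST_PRIMARY, CodeRole.DISTANT_SECONDARY, CodeRole.REGIONAL_NODE_SECONDARY)
    ]
    malignancy_dates += [
        r.diagnosis_date
        for r in history.other_registrations
        if _safe_role(r.site_code, config) is CodeRole.BREAST_PRIMARY
        and r.diagnosis_date > history.index_date
    ]
    out: list[CandidateOutcome] = []
    for cand in candidates:
        if not cand.rule_id.startswith("procedure.") or cand.outcome not in (
            OutcomeType.LOCOREGIONAL_RECURRENCE,
            OutcomeType.CONTRALATERAL_BREAST_CANCER,
        ):
            out.append(cand)
            continue
        proc = cand.evidence[0]
        if code_matches(proc.code, config.reconstruction_codes):
            logger.debug(
                "patient %s: dropped %s at %s (reconstruction code %s)",
                cand.patient_id, cand.outcome.value, cand.date, proc.code,
            )
            continue
        if not any(
            abs((proc.date - d).days) <= THREE_MONTHS_DAYS for d in malignancy_dates
        ):
            logger.debug(
                "patient %s: dropped %s at %s (no malignancy code within 91 d of surgery)",
                cand.patient_id, cand.outcome.value, cand.date,
            )
            continue
        out.append(cand)
    return out


def _is_single_day(ev: CodedEvent) -> bool:
    try:
        return int(ev.attributes.get("duration_days", "1")) <= 1
    except (TypeError, ValueError):
        return True


def _infusion_runs(events: Sequence[CodedEvent], config: EngineConfig) -> list[list[CodedEvent]]:
    """Maximal runs of single-day systemic attendances whose successive
    gaps all fall inside [min_gap, max_gap]."""
    runs: list[list[CodedEvent]] = []
    for ev in events:
        if runs:
            gap = (ev.date - runs[-1][-1].date).days
            if config.infusion_min_gap_days <= gap <= config.infusion_max_gap_days:
                runs[-1].append(ev)
                continue
        runs.append([ev])
    return runs


def infusion_filter(
    history: PatientHistory,
    candidates: Sequence[CandidateOutcome],
    config: EngineConfig,
) -> list[CandidateOutcome]:
    """Remove distant-recurrence candidates explained by a regular
    single-day infusion schedule.

    The trigger series must contain at least ``infusion_min_count``
    attendances with successive gaps in the configured band, and no
    metastasis diagnosis code may occur within ±91 days of any attendance
    in the series.
    """
    systemic = [
        e
        for e in _therapy_events(history)
        if normalize_code(e.code) == CHEMOTHERAPY and _is_single_day(e)
    ]
    runs = _infusion_runs(systemic, config)
    met_dates = [
        e.date
        for e in _diagnosis_events(history)
        if _safe_role(e.code, config) is CodeRole.DISTANT_SECONDARY
    ]

    def run_of(ev: CodedEvent) -> Optional[list[CodedEvent]]:
        for run in runs:
            if ev in run:
                return run
        return None

    out: list[CandidateOutcome] = []
    for cand in candidates:
        if cand.outcome is not OutcomeType.DISTANT_RECURRENCE or not cand.rule_id.startswith(
            "therapy."
        ):
            out.append(cand)
            continue
        evidence_events = [e for e in cand.evidence if isinstance(e, CodedEvent)]
        if not evidence_events or not all(
            e.system is CodingSystem.TREATMENT
            and normalize_code(e.code) == CHEMOTHERAPY
            and _is_single_day(e)
            for e in evidence_events
        ):
            out.append(cand)
            continue
        run = run_of(evidence_events[0])
        if (
            run is not None
            and len(run) >= config.infusion_min_count
            and all(e in run for e in evidence_events)
            and not any(
                abs((e.date - d).days) <= THREE_MONTHS_DAYS for e in run for d in met_dates
            )
        ):
            logger.debug(
                "patient %s: dropped DISTANT_RECURRENCE at %s (regular infusion series, n=%d)",
                cand.patient_id, cand.date, len(run),
            )
            continue
        out.append(cand)
    return out


def apply_post_validation_adjustment(
    candidates: Sequence[CandidateOutcome], index_date: Date
) -> list[CandidateOutcome]:
    """Ignore locoregional, unknown-type and contralateral events dated
    within the first year (365 days, half-open) after diagnosis."""
    cutoff = index_date + timedelta(days=ONE_YEAR_DAYS)
    suppressed = {
        OutcomeType.LOCOREGIONAL_RECURRENCE,
        OutcomeType.RECURRENCE_TYPE_UNKNOWN,
        OutcomeType.CONTRALATERAL_BREAST_CANCER,
    }
    return [c for c in candidates if not (c.outcome in suppressed and c.date < cutoff)]


def resolve_same_date(
    candidates: Sequence[CandidateOutcome],
    priority: Optional[PriorityOrder] = None,
) -> list[CandidateOutcome]:
    """Keep one candidate per (patient, date): the one of best priority,
    with the evidence of the discarded same-date candidates merged in."""
    priority = priority or PriorityOrder()
    groups: dict[tuple[str, Date], list[CandidateOutcome]] = {}
    for cand in candidates:
        groups.setdefault((cand.patient_id, cand.date), []).append(cand)
    out: list[CandidateOutcome] = []
    for key in sorted(groups):
        group = sorted(
            groups[key], key=lambda c: (priority.rank(c.outcome), c.rule_id)
        )
        winner = group[0]
        merged: list = list(winner.evidence)
        for other in group[1:]:
            for ev in other.evidence:
                if ev not in merged:
                    merged.append(ev)
        out.append(replace(winner, evidence=tuple(merged)))
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class AlgorithmResult:
    """Chronologically sorted events for one woman, with evidence chains."""

    patient_id: str
    events: list[CandidateOutcome]

    def outcome_events(self) -> list:
        from .model import OutcomeEvent

        return [OutcomeEvent(self.patient_id, c.date, c.outcome) for c in self.events]

    def first_event(
        self, definition, window: Optional[FollowUpWindow] = None
    ):
        """Earliest surviving event matching an outcome definition inside
        the window, applying the definition's censor/ignore semantics.
        Returns a (CandidateOutcome | None, censored_date | None) pair via
        the metrics layer's side-status logic."""
        from .metrics import side_status

        return side_status(self.outcome_events(), definition, window)


def run_algorithm(history: PatientHistory, config: Optional[EngineConfig] = None) -> AlgorithmResult:
    """Run the full pipeline on one woman's history."""
    config = config or EngineConfig()
    candidates: list[CandidateOutcome] = []
    candidates += candidates_from_registrations(history, config)
    candidates += candidates_from_diagnosis_codes(history, config)
    candidates += candidates_from_procedures(history, config)
    candidates += candidates_from_therapy(history, config)
    candidates += candidates_from_death(history, config)

    if config.reconstruction_filter_enabled:
        candidates = reconstruction_filter(candidates, history, config)
    if config.infusion_filter_enabled:
        candidates = infusion_filter(history, candidates, config)
    if config.adjustment_flag:
        candidates = apply_post_validation_adjustment(candidates, history.index_date)
    candidates = resolve_same_date(candidates, config.priority)
    candidates.sort(key=lambda c: (c.date, config.priority.rank(c.outcome)))
    return AlgorithmResult(history.patient_id, candidates)
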