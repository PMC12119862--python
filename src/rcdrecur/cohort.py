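"""Training-population selection and follow-up-window construction.

A woman enters the training population if her first invasive breast
cancer (IBC) registration falls inside the accrual window and none of the
exclusion rules fires: an earlier IBC, an earlier non-breast invasive
cancer (non-melanoma skin cancer never excludes), a synchronous
opposite-breast IBC, or a synchronous other-site invasive primary —
"synchronous" meaning within three months (91 days) of the index date.

Follow-up runs from the index diagnosis to the earliest of death,
emigration, or the end of the study period; validation follow-up runs
from randomisation to the last trial visit plus a 3-month window.
All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from datetime import date as Date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    CodeConfig,
    CodeRole,
    Laterality,
    PatientHistory,
    TumourRegistration,
    classify_diagnosis_code,
    opposite_laterality,
)

logger = logging.getLogger(__name__)

#: Fixed day-count conventions: "three months" and "one year".
THREE_MONTHS_DAYS = 91
ONE_YEAR_DAYS = 365


class EndReason(enum.Enum):
    DEATH = "DEATH"
    EMIGRATION = "EMIGRATION"
    STUDY_END = "STUDY_END"
    LAST_VISIT_PLUS_WINDOW = "LAST_VISIT_PLUS_WINDOW"


@dataclass(frozen=True)
class FollowUpWindow:
    start: Date
    end: Date
    end_reason: EndReason

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("follow-up window start must not exceed end")


class ExclusionReason(enum.Enum):
    PRIOR_IBC = "PRIOR_IBC"
    PRIOR_OTHER_INVASIVE = "PRIOR_OTHER_INVASIVE"
    SYNCHRONOUS_BILATERAL = "SYNCHRONOUS_BILATERAL"
    SYNCHRONOUS_OTHER_PRIMARY = "SYNCHRONOUS_OTHER_PRIMARY"


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    reason: ExclusionReason
    triggering_registration: str  # tumour_id


def _safe_role(reg: TumourRegistration, config: CodeConfig) -> CodeRole:
    try:
        return classify_diagnosis_code(reg.site_code, config)
    except ValueError:
        logger.warning(
            "patient %s: unparseable site code %r on tumour %s treated as non-malignant",
            reg.patient_id,
            reg.site_code,
            reg.tumour_id,
        )
        return CodeRole.NON_MALIGNANT


def _is_ibc(reg: TumourRegistration, config: CodeConfig) -> bool:
    return (
        reg.behaviour.value == "INVASIVE"
        and _safe_role(reg, config) is CodeRole.BREAST_PRIMARY
    )


def select_training_population(
    registrations: Mapping[str, Sequence[TumourRegistration]],
    window_start: Date,
    window_end: Date,
    config: Optional[CodeConfig] = None,
) -> tuple[list[str], list[ExclusionRecord]]:
    """Select women for the training population.

    ``registrations`` maps patient_id to that woman's registrations
    (any order; sorted internally, so the result is order-independent).
    Returns the included patient ids (sorted) and one ExclusionRecord per
    excluded woman, carrying the first matching reason in the fixed order
    PRIOR_IBC, PRIOR_OTHER_INVASIVE, SYNCHRONOUS_BILATERAL,
    SYNCHRONOUS_OTHER_PRIMARY.

    Women whose first IBC falls outside ``[window_start, window_end)``
    are simply not part of the candidate population (no record emitted).
    """
    if window_start >= window_end:
        raise ValueError("window_start must precede window_end")
    config = config or CodeConfig()
    included: list[str] = []
    excluded: list[ExclusionRecord] = []

    for pid in sorted(registrations):
        regs = sorted(
            registrations[pid], key=lambda r: (r.diagnosis_date, r.tumour_id)
        )
        ibc = [r for r in regs if _is_ibc(r, config)]
        if not ibc:
            continue
        index = ibc[0]
        if not (window_start <= index.diagnosis_date < window_end):
            # first IBC outside accrual window: if it is *before* the
            # window she is an excluded prior-IBC case; after, she is
            # simply not a candidate.
            if index.diagnosis_date < window_start:
                excluded.append(
                    ExclusionRecord(pid, ExclusionReason.PRIOR_IBC, index.tumour_id)
                )
            continue

        record = _first_exclusion(pid, index, regs, config)
        if record is None:
            included.append(pid)
        else:
            excluded.append(record)
    return included, excluded


def _first_exclusion(
    pid: str,
    index: TumourRegistration,
    regs: Sequence[TumourRegistration],
    config: CodeConfig,
) -> Optional[ExclusionRecord]:
    idx_date = index.diagnosis_date
    synch_end = idx_date + timedelta(days=THREE_MONTHS_DAYS)
    opp = opposite_laterality(index.laterality)

    # PRIOR_IBC covered by first-IBC-in-window selection; an earlier IBC
    # would itself be the index, outside the window.
    for reg in regs:
        if reg is index:
            continue
        role = _safe_role(reg, config)
        invasive = reg.behaviour.value == "INVASIVE"
        if not invasive or role in (CodeRole.IGNORED_NMSC, CodeRole.NON_MALIGNANT):
            continue
        if reg.diagnosis_date < idx_date and role is not CodeRole.BREAST_PRIMARY:
            return ExclusionRecord(pid, ExclusionReason.PRIOR_OTHER_INVASIVE, reg.tumour_id)

    for reg in regs:
        if reg is index:
            continue
        if (
            _is_ibc(reg, config)
            and idx_date <= reg.diagnosis_date <= synch_end
            and (opp is None or reg.laterality in (opp, Laterality.BILATERAL))
            and reg.laterality is not index.laterality
        ):
            return ExclusionRecord(pid, ExclusionReason.SYNCHRONOUS_BILATERAL, reg.tumour_id)

    for reg in regs:
        if reg is index:
            continue
        role = _safe_role(reg, config)
        if (
            reg.behaviour.value == "INVASIVE"
            and role not in (CodeRole.BREAST_PRIMARY, CodeRole.IGNORED_NMSC, CodeRole.NON_MALIGNANT)
            and idx_date <= reg.diagnosis_date <= synch_end
        ):
            return ExclusionRecord(pid, ExclusionReason.SYNCHRONOUS_OTHER_PRIMARY, reg.tumour_id)
    return None


def follow_up_window(history: PatientHistory, study_end: Date) -> FollowUpWindow:
    """Follow-up from index diagnosis to min(death, emigration, study end).

    Ties are broken DEATH > EMIGRATION > STUDY_END.
    """
    start = history.index_date
    if start > study_end:
        raise ValueError(
            f"patient {history.patient_id}: index date {start} after study end {study_end}"
        )
    bounds: list[tuple[Date, EndReason]] = [(study_end, EndReason.STUDY_END)]
    if history.emigration_date is not None:
        bounds.append((history.emigration_date, EndReason.EMIGRATION))
    if history.death is not None:
        bounds.append((history.death.death_date, EndReason.DEATH))
    priority = {EndReason.DEATH: 0, EndReason.EMIGRATION: 1, EndReason.STUDY_END: 2}
    end, reason = min(bounds, key=lambda b: (b[0], priority[b[1]]))
    return FollowUpWindow(start, end, reason)


def validation_window(randomisation: Date, last_visit: Date) -> FollowUpWindow:
    """Validation follow-up: randomisation to last visit + 91 days."""
    if last_visit < randomisation:
        raise ValueError(
            f"last visit {last_visit} precedes randomisation {randomisation}"
        )
    return FollowUpWindow(
        randomisation,
        last_visit + timedelta(days=THREE_MONTHS_DAYS),
        EndReason.LAST_VISIT_PLUS_WINDOW,
    )
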