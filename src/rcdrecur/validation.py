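"""End-to-end validation orchestration.

Given per-woman gold-standard events (with follow-up windows) and
per-woman engine output, builds the agreement tables, performance
metrics, date-difference distributions, first-event cross-tabulation and
Kaplan–Meier curves for each outcome definition and landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import FollowUpWindow, ONE_YEAR_DAYS, validation_window
from .metrics import (
    AgreementTable,
    DEFAULT_DEFINITIONS,
    KMCurve,
    OutcomeDefinition,
    PairClass,
    PerformanceMetrics,
    classify_pair,
    compatibility_summary,
    date_diff_distribution,
    first_event_crosstab,
    km_risk,
    performance,
    side_status,
    within_window_performance,
)
from .model import OutcomeEvent, OutcomeType, PriorityOrder
from .synthcohort import DAYS_PER_YEAR, TruthRecord

__all__ = [
    "AgreementBlock",
    "ValidationReport",
    "first_event_of_any_type",
    "run_validation",
    "km_inputs_from_truth",
    "km_inputs_from_events",
]


def first_event_of_any_type(
    events: Sequence[OutcomeEvent],
    window: Optional[FollowUpWindow] = None,
    priority: Optional[PriorityOrder] = None,
) -> Optional[OutcomeType]:
    """Earliest event of any type inside the window; same-date ties are
    broken by the outcome priority order."""
    priority = priority or PriorityOrder()
    eligible = [
        e
        for e in events
        if window is None or (window.start <= e.date < window.end)
    ]
    if not eligible:
        return None
    first = min(eligible, key=lambda e: (e.date, priority.rank(e.outcome)))
    return first.outcome


@dataclass
class AgreementBlock:
    """One analysis cell: a definition × landmark agreement table with
    its performance metrics and date-difference distribution."""

    definition: str
    landmark_years: Optional[float]
    table: AgreementTable
    perf: PerformanceMetrics
    perf_within_window: PerformanceMetrics
    date_bins: pd.DataFrame


@dataclass
class ValidationReport:
    blocks: dict = field(default_factory=dict)  # (definition, landmark) -> AgreementBlock
    crosstab: Optional[pd.DataFrame] = None
    compatibility: dict = field(default_factory=dict)
    km: dict = field(default_factory=dict)  # (definition, side) -> KMCurve

    def block(self, definition: str, landmark: Optional[float] = None) -> AgreementBlock:
        return self.blocks[(definition, landmark)]


def run_validation(
    windows: Mapping[str, FollowUpWindow],
    gold_events: Mapping[str, Sequence[OutcomeEvent]],
    rcd_events: Mapping[str, Sequence[OutcomeEvent]],
    definitions: Optional[Mapping[str, OutcomeDefinition]] = None,
    landmarks: Sequence[Optional[float]] = (None,),
    match_window_days: int = 182,
    km_horizons: Sequence[float] = (1, 3, 5, 10),
) -> ValidationReport:
    """Compare gold and RCD sides woman by woman.

    ``windows`` maps patient id to her validation follow-up window; the
    three event maps must cover the same women (missing entries mean no
    events on that side).
    """
    definitions = definitions or DEFAULT_DEFINITIONS
    report = ValidationReport()
    pids = sorted(windows)
    for name, definition in definitions.items():
        for lm in landmarks:
            pairs = [
                classify_pair(
                    pid,
                    gold_events.get(pid, ()),
                    rcd_events.get(pid, ()),
                    definition,
                    windows[pid],
                    landmark_years=lm,
                )
                for pid in pids
            ]
            table = AgreementTable.from_pairs(pairs)
            report.blocks[(name, lm)] = AgreementBlock(
                definition=name,
                landmark_years=lm,
                table=table,
                perf=performance(table),
                perf_within_window=within_window_performance(
                    table, match_window_days=match_window_days
                ),
                date_bins=date_diff_distribution(table.diffs),
            )
        for side, events in (("gold", gold_events), ("rcd", rcd_events)):
            durations, observed = km_inputs_from_events(
                {pid: events.get(pid, ()) for pid in pids},
                definition,
                windows,
            )
            if durations:
                report.km[(name, side)] = km_risk(durations, observed, km_horizons)

    gold_first = {
        pid: first_event_of_any_type(gold_events.get(pid, ()), windows[pid]) for pid in pids
    }
    rcd_first = {
        pid: first_event_of_any_type(rcd_events.get(pid, ()), windows[pid]) for pid in pids
    }
    report.crosstab = first_event_crosstab(gold_first, rcd_first)
    report.compatibility = compatibility_summary(report.crosstab)
    return report


def km_inputs_from_events(
    events: Mapping[str, Sequence[OutcomeEvent]],
    definition: OutcomeDefinition,
    windows: Mapping[str, FollowUpWindow],
) -> tuple[list[float], list[bool]]:
    """Per-woman (duration in days since window start, event observed)
    under a definition: qualifying first event, else censoring at the
    first censoring-type event or at window end."""
    durations: list[float] = []
    observed: list[bool] = []
    for pid, evs in events.items():
        window = windows[pid]
        status, d = side_status(evs, definition, window)
        if status == "EVENT":
            durations.append((d - window.start).days)
            observed.append(True)
        else:
            censor = window.end
            for ev in sorted(evs, key=lambda e: e.date):
                if ev.outcome in definition.censoring and window.start <= ev.date < window.end:
                    censor = ev.date
                    break
            durations.append((censor - window.start).days)
            observed.append(False)
    return durations, observed


_TRUTH_FIELDS = {
    "distant": "distant_date",
    "locoregional": "locoregional_date",
    "contralateral": "contralateral_date",
}


def km_inputs_from_truth(
    truths: Sequence[TruthRecord], outcome: str, horizon_years: float = 10.0
) -> tuple[list[float], list[bool]]:
    """Truth-side KM inputs for one latent outcome: event at its true
    date, otherwise censoring at the earlier of death and the follow-up
    horizon.  For ``outcome="all_cause_death"`` the event is death."""
    durations: list[float] = []
    observed: list[bool] = []
    horizon = horizon_years * DAYS_PER_YEAR
    for t in truths:
        death_day = (
            (t.death_date - t.randomisation_date).days if t.death_date is not None else None
        )
        if outcome == "all_cause_death":
            if death_day is not None and death_day <= horizon:
                durations.append(death_day)
                observed.append(True)
            else:
                durations.append(horizon)
                observed.append(False)
            continue
        event_date = getattr(t, _TRUTH_FIELDS[outcome])
        censor = min(horizon, death_day) if death_day is not None else horizon
        if event_date is not None:
            day = (event_date - t.randomisation_date).days
            durations.append(day)
            observed.append(True)
        else:
            durations.append(censor)
            observed.append(False)
    return durations, observed


def windows_from_truth(truths: Sequence[TruthRecord]) -> dict[str, FollowUpWindow]:
    return {
        t.patient_id: validation_window(t.randomisation_date, t.last_visit_date)
        for t in truths
    }
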