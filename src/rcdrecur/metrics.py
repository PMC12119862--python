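"""Validation of algorithm output against gold-standard follow-up.

Per-woman first events from the routinely collected data (RCD) are
compared with trial-style gold-standard follow-up under an *outcome
definition* that says which outcome types qualify, which censor and
which are ignored.  Women are cross-classified (event in both / one
side / neither, or censored before the analysis period), diagnostic
accuracy is summarised as sensitivity/specificity/PPV/NPV with Wald
95% confidence intervals, matched event dates are binned, first events
are cross-tabulated over the full taxonomy, and cumulative risks are
estimated with the Kaplan–Meier product-limit method (via lifelines),
including a delayed-entry variant for landmark analyses.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import FollowUpWindow, ONE_YEAR_DAYS
from .model import OutcomeEvent, OutcomeType, RECURRENCE_TYPES

__all__ = [
    "OutcomeDefinition",
    "DEFAULT_DEFINITIONS",
    "PairClassLabel",
    "PairClass",
    "AgreementTable",
    "PerformanceMetrics",
    "KMCurve",
    "side_status",
    "classify_pair",
    "build_agreement_table",
    "performance",
    "within_window_performance",
    "date_diff_distribution",
    "first_event_crosstab",
    "compatibility_summary",
    "km_risk",
]

#: Date-agreement bin cut points (days): "<6 months" and "6–12 months".
SIX_MONTHS_DAYS = 182


@dataclass(frozen=True)
class OutcomeDefinition:
    """Which outcome types qualify, censor, or are ignored for an analysis."""

    name: str
    qualifying: frozenset
    censoring: frozenset
    ignored: frozenset = frozenset()

    def __post_init__(self):
        q, c, i = set(self.qualifying), set(self.censoring), set(self.ignored)
        if (q & c) or (q & i) or (c & i):
            raise ValueError(f"definition {self.name}: qualifying/censoring/ignored overlap")


def _defs() -> dict[str, OutcomeDefinition]:
    O = OutcomeType
    deaths = {O.BREAST_CANCER_DEATH, O.NON_BREAST_CANCER_DEATH}
    return {
        "DISTANT_RECURRENCE": OutcomeDefinition(
            "DISTANT_RECURRENCE",
            qualifying=frozenset({O.DISTANT_RECURRENCE}),
            censoring=frozenset(deaths | {O.NON_BREAST_MALIGNANCY}),
            ignored=frozenset(
                {O.LOCOREGIONAL_RECURRENCE, O.RECURRENCE_TYPE_UNKNOWN, O.CONTRALATERAL_BREAST_CANCER}
            ),
        ),
        # locoregional as analysed: counted only when recorded before any
        # distant recurrence, so a distant event censors
        "LOCOREGIONAL_RECURRENCE": OutcomeDefinition(
            "LOCOREGIONAL_RECURRENCE",
            qualifying=frozenset({O.LOCOREGIONAL_RECURRENCE}),
            censoring=frozenset(deaths | {O.DISTANT_RECURRENCE, O.NON_BREAST_MALIGNANCY}),
            ignored=frozenset({O.RECURRENCE_TYPE_UNKNOWN, O.CONTRALATERAL_BREAST_CANCER}),
        ),
        "CONTRALATERAL": OutcomeDefinition(
            "CONTRALATERAL",
            qualifying=frozenset({O.CONTRALATERAL_BREAST_CANCER}),
            censoring=frozenset(deaths | {O.DISTANT_RECURRENCE, O.NON_BREAST_MALIGNANCY}),
            ignored=frozenset({O.LOCOREGIONAL_RECURRENCE, O.RECURRENCE_TYPE_UNKNOWN}),
        ),
        "ANY_RECURRENCE": OutcomeDefinition(
            "ANY_RECURRENCE",
            qualifying=frozenset(RECURRENCE_TYPES),
            censoring=frozenset(deaths | {O.NON_BREAST_MALIGNANCY}),
        ),
        "BREAST_CANCER_MORTALITY": OutcomeDefinition(
            "BREAST_CANCER_MORTALITY",
            qualifying=frozenset({O.BREAST_CANCER_DEATH}),
            censoring=frozenset({O.NON_BREAST_CANCER_DEATH}),
            ignored=frozenset(RECURRENCE_TYPES | {O.NON_BREAST_MALIGNANCY}),
        ),
        "ALL_CAUSE_MORTALITY": OutcomeDefinition(
            "ALL_CAUSE_MORTALITY",
            qualifying=frozenset(deaths),
            censoring=frozenset(),
            ignored=frozenset(RECURRENCE_TYPES | {O.NON_BREAST_MALIGNANCY}),
        ),
    }


DEFAULT_DEFINITIONS: Mapping[str, OutcomeDefinition] = _defs()


class PairClassLabel(enum.Enum):
    EVENT_BOTH = "EVENT_BOTH"
    EVENT_TRIAL_ONLY = "EVENT_TRIAL_ONLY"
    EVENT_RCD_ONLY = "EVENT_RCD_ONLY"
    NO_EVENT_EITHER = "NO_EVENT_EITHER"
    CENSORED_TRIAL_ONLY = "CENSORED_TRIAL_ONLY"
    CENSORED_RCD_ONLY = "CENSORED_RCD_ONLY"
    CENSORED_BOTH = "CENSORED_BOTH"


@dataclass(frozen=True)
class PairClass:
    patient_id: str
    label: PairClassLabel
    date_gold: Optional[Date] = None
    date_rcd: Optional[Date] = None

    def __post_init__(self):
        has_gold = self.label in (PairClassLabel.EVENT_BOTH, PairClassLabel.EVENT_TRIAL_ONLY)
        has_rcd = self.label in (PairClassLabel.EVENT_BOTH, PairClassLabel.EVENT_RCD_ONLY)
        if has_gold != (self.date_gold is not None) or has_rcd != (self.date_rcd is not None):
            raise ValueError("pair dates must be present iff the corresponding side has an event")


def side_status(
    events: Sequence[OutcomeEvent],
    definition: OutcomeDefinition,
    window: Optional[FollowUpWindow] = None,
    landmark: Optional[Date] = None,
) -> tuple[str, Optional[Date]]:
    """Resolve one side's first-event status under a definition.

    Scans date-sorted events; ignored outcomes are skipped, the first
    qualifying or censoring outcome decides.  Returns one of
    ``("EVENT", date)``, ``("NO_EVENT", None)`` or
    ``("CENSORED_BEFORE", None)`` relative to the analysis period
    ``[max(window.start, landmark), window.end)``; an event or censoring
    strictly before the landmark censors the woman before the period,
    an event exactly at the landmark counts inside.
    """
    start = window.start if window else None
    end = window.end if window else None
    lm = landmark if landmark is not None else start
    if end is not None and lm is not None and end <= lm:
        return ("CENSORED_BEFORE", None)
    for ev in sorted(events, key=lambda e: e.date):
        if ev.outcome in definition.ignored:
            continue
        if start is not None and ev.date < start:
            continue
        if end is not None and ev.date >= end:
            break
        if ev.outcome in definition.qualifying:
            if lm is not None and ev.date < lm:
                return ("CENSORED_BEFORE", None)
            return ("EVENT", ev.date)
        if ev.outcome in definition.censoring:
            if lm is not None and ev.date < lm:
                return ("CENSORED_BEFORE", None)
            return ("NO_EVENT", None)
    return ("NO_EVENT", None)


def classify_pair(
    patient_id: str,
    gold_events: Sequence[OutcomeEvent],
    rcd_events: Sequence[OutcomeEvent],
    definition: OutcomeDefinition,
    window: FollowUpWindow,
    landmark_years: Optional[float] = None,
) -> PairClass:
    """Cross-classify one woman's gold and RCD sides.

    ``landmark_years`` shifts the analysis-period start to
    ``window.start + round(365 * years)`` days; a side whose qualifying
    or censoring event precedes the landmark is censored before the
    period on that side.
    """
    landmark = None
    if landmark_years is not None:
        landmark = window.start + timedelta(days=round(ONE_YEAR_DAYS * landmark_years))
    g_status, g_date = side_status(gold_events, definition, window, landmark)
    r_status, r_date = side_status(rcd_events, definition, window, landmark)

    if g_status == "CENSORED_BEFORE" or r_status == "CENSORED_BEFORE":
        if g_status == r_status:
            label = PairClassLabel.CENSORED_BOTH
        elif g_status == "CENSORED_BEFORE":
            label = PairClassLabel.CENSORED_TRIAL_ONLY
        else:
            label = PairClassLabel.CENSORED_RCD_ONLY
        return PairClass(patient_id, label)
    if g_status == "EVENT" and r_status == "EVENT":
        return PairClass(patient_id, PairClassLabel.EVENT_BOTH, g_date, r_date)
    if g_status == "EVENT":
        return PairClass(patient_id, PairClassLabel.EVENT_TRIAL_ONLY, date_gold=g_date)
    if r_status == "EVENT":
        return PairClass(patient_id, PairClassLabel.EVENT_RCD_ONLY, date_rcd=r_date)
    return PairClass(patient_id, PairClassLabel.NO_EVENT_EITHER)


@dataclass
class AgreementTable:
    """Per-class counts plus matched-pair date differences (days,
    RCD minus gold)."""

    counts: dict = field(default_factory=dict)
    diffs: list[int] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[PairClass]) -> "AgreementTable":
        table = cls(counts={label: 0 for label in PairClassLabel})
        for p in pairs:
            table.counts[p.label] += 1
            if p.label is PairClassLabel.EVENT_BOTH:
                table.diffs.append((p.date_rcd - p.date_gold).days)
        return table

    @classmethod
    def from_counts(
        cls,
        event_both: int,
        event_trial_only: int,
        event_rcd_only: int,
        no_event_either: int,
        censored_trial_only: int = 0,
        censored_rcd_only: int = 0,
        censored_both: int = 0,
        diffs: Optional[Sequence[int]] = None,
    ) -> "AgreementTable":
        counts = {
            PairClassLabel.EVENT_BOTH: event_both,
            PairClassLabel.EVENT_TRIAL_ONLY: event_trial_only,
            PairClassLabel.EVENT_RCD_ONLY: event_rcd_only,
            PairClassLabel.NO_EVENT_EITHER: no_event_either,
            PairClassLabel.CENSORED_TRIAL_ONLY: censored_trial_only,
            PairClassLabel.CENSORED_RCD_ONLY: censored_rcd_only,
            PairClassLabel.CENSORED_BOTH: censored_both,
        }
        return cls(counts=counts, diffs=list(diffs or []))

    def __getitem__(self, label: PairClassLabel) -> int:
        return self.counts[label]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Estimate:
    """A percentage with its Wald 95% confidence interval."""

    value: Optional[float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    def round1(self) -> tuple:
        r = lambda x: None if x is None else _round_half_away(x, 1)
        return (r(self.value), r(self.lower), r(self.upper))


def _round_half_away(x: float, ndigits: int) -> float:
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _wald(numer: int, denom: int) -> Estimate:
    """Wald normal-approximation CI on a proportion, as a percentage,
    clipped to [0, 100].  Zero denominator → undefined (None)."""
    if denom == 0:
        return Estimate(None)
    p = numer / denom
    se = math.sqrt(p * (1 - p) / denom)
    z = 1.959963984540054  # standard normal 97.5% quantile
    lo = max(0.0, p - z * se)
    hi = min(1.0, p + z * se)
    return Estimate(100 * p, 100 * lo, 100 * hi)


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate


def performance(table: AgreementTable) -> PerformanceMetrics:
    """Diagnostic accuracy of the RCD against the gold standard.

    Censored-before-period classes are excluded from every denominator.
    """
    tp = table[PairClassLabel.EVENT_BOTH]
    fn = table[PairClassLabel.EVENT_TRIAL_ONLY]
    fp = table[PairClassLabel.EVENT_RCD_ONLY]
    tn = table[PairClassLabel.NO_EVENT_EITHER]
    return PerformanceMetrics(
        sensitivity=_wald(tp, tp + fn),
        specificity=_wald(tn, tn + fp),
        ppv=_wald(tp, tp + fp),
        npv=_wald(tn, tn + fn),
    )


def within_window_performance(
    table: AgreementTable,
    diffs: Optional[Sequence[int]] = None,
    match_window_days: int = SIX_MONTHS_DAYS,
) -> PerformanceMetrics:
    """Performance counting only date-matched detections as true positives.

    Matched pairs whose dates differ by more than ``match_window_days``
    are treated as missed (false negatives for sensitivity and NPV) but
    their RCD events are not added to the false-positive cell, so
    specificity is unchanged; PPV's numerator is restricted to
    within-window matches.
    """
    diffs = list(table.diffs if diffs is None else diffs)
    tp_all = table[PairClassLabel.EVENT_BOTH]
    if len(diffs) != tp_all:
        raise ValueError("need one date difference per matched pair")
    tp = sum(1 for d in diffs if abs(d) <= match_window_days)
    late = tp_all - tp
    fn = table[PairClassLabel.EVENT_TRIAL_ONLY] + late
    fp = table[PairClassLabel.EVENT_RCD_ONLY]
    tn = table[PairClassLabel.NO_EVENT_EITHER]
    return PerformanceMetrics(
        sensitivity=_wald(tp, tp + fn),
        specificity=_wald(tn, tn + fp),
        ppv=_wald(tp, tp + fp),
        npv=_wald(tn, tn + fn),
    )


def date_diff_distribution(diffs: Sequence[int]) -> pd.DataFrame:
    """Counts and percentages of |date difference| in the bins
    <6 months, 6–12 months, >1 year (cut points 182 and 365 days)."""
    a = np.abs(np.asarray(list(diffs), dtype=int))
    counts = {
        "<6 months": int((a <= SIX_MONTHS_DAYS).sum()),
        "6-12 months": int(((a > SIX_MONTHS_DAYS) & (a <= ONE_YEAR_DAYS)).sum()),
        ">1 year": int((a > ONE_YEAR_DAYS).sum()),
    }
    total = len(a)
    pct = {k: (100 * v / total if total else float("nan")) for k, v in counts.items()}
    return pd.DataFrame({"count": counts, "percent": pct})


NO_EVENT = "NO_EVENT"
_CROSSTAB_ORDER = [o.value for o in OutcomeType] + [NO_EVENT]


def first_event_crosstab(
    gold_first: Mapping[str, Optional[OutcomeType]],
    rcd_first: Mapping[str, Optional[OutcomeType]],
) -> pd.DataFrame:
    """8×8 cross-tabulation of per-woman first events (7 outcome types
    plus "no event"), gold standard in rows, RCD in columns."""
    if set(gold_first) != set(rcd_first):
        raise ValueError("gold and RCD rosters differ")
    tab = pd.DataFrame(0, index=_CROSSTAB_ORDER, columns=_CROSSTAB_ORDER, dtype=int)
    for pid in gold_first:
        g = gold_first[pid].value if gold_first[pid] is not None else NO_EVENT
        r = rcd_first[pid].value if rcd_first[pid] is not None else NO_EVENT
        tab.loc[g, r] += 1
    return tab


def compatibility_summary(tab: pd.DataFrame) -> dict[str, float]:
    """Headline agreement fractions from a first-event cross-tabulation.

    Recurrence of unknown type in the RCD is treated as compatible with
    either recurrence type.  Returns percentages:

    - ``rcd_missed_pct``: women with a gold event but no RCD event;
    - ``locoregional_compatible_pct`` / ``distant_compatible_pct``:
      gold locoregional (distant) first events whose first RCD event is
      the same type or unknown-type;
    - ``unknown_compatible_pct``: gold unknown-type first events whose
      first RCD event is any of the three recurrence categories;
    - ``other_same_pct``: gold contralateral/death/non-breast events
      with the identical first RCD event.
    """
    O = OutcomeType
    lr, dr, unk = (
        O.LOCOREGIONAL_RECURRENCE.value,
        O.DISTANT_RECURRENCE.value,
        O.RECURRENCE_TYPE_UNKNOWN.value,
    )
    event_rows = [r for r in _CROSSTAB_ORDER if r != NO_EVENT]
    n_events = int(tab.loc[event_rows].to_numpy().sum())
    missed = int(tab.loc[event_rows, NO_EVENT].sum())

    def pct(n, d):
        return 100 * n / d if d else float("nan")

    out = {"rcd_missed_pct": pct(missed, n_events)}
    out["locoregional_compatible_pct"] = pct(
        int(tab.loc[lr, [lr, unk]].sum()), int(tab.loc[lr].sum())
    )
    out["distant_compatible_pct"] = pct(
        int(tab.loc[dr, [dr, unk]].sum()), int(tab.loc[dr].sum())
    )
    out["unknown_compatible_pct"] = pct(
        int(tab.loc[unk, [lr, dr, unk]].sum()), int(tab.loc[unk].sum())
    )
    other = [
        O.CONTRALATERAL_BREAST_CANCER.value,
        O.BREAST_CANCER_DEATH.value,
        O.NON_BREAST_MALIGNANCY.value,
        O.NON_BREAST_CANCER_DEATH.value,
    ]
    same = sum(int(tab.loc[r, r]) for r in other)
    out["other_same_pct"] = pct(same, int(tab.loc[other].to_numpy().sum()))
    return out


@dataclass
class KMCurve:
    """Cumulative risk (percent) with Greenwood-based 95% CI at the
    requested horizons (years)."""

    horizons: list[float]
    risk: list[Optional[float]]
    lower: list[Optional[float]]
    upper: list[Optional[float]]
    fitter: KaplanMeierFitter

    def risk_at(self, horizon: float) -> Optional[float]:
        return self.risk[self.horizons.index(horizon)]


def km_risk(
    durations_days: Sequence[float],
    observed: Sequence[bool],
    horizons_years: Sequence[float] = (1, 3, 5, 10),
    entry_days: Optional[Sequence[float]] = None,
) -> KMCurve:
    """Kaplan–Meier cumulative risk (1 − survival) at fixed horizons.

    ``durations_days``/``observed`` follow the usual survival encoding;
    ``entry_days`` enables delayed entry for landmark analyses (women at
    risk only from their entry time).  Horizons beyond the last time at
    which anyone remains at risk are reported as undefined (None).
    """
    durations = np.asarray(durations_days, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("no women contribute to the curve")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, observed, entry=np.asarray(entry_days, dtype=float) if entry_days is not None else None)
    max_t = durations.max()
    risks: list[Optional[float]] = []
    los: list[Optional[float]] = []
    his: list[Optional[float]] = []
    ci = kmf.confidence_interval_survival_function_
    for h in horizons_years:
        t = h * ONE_YEAR_DAYS
        if t > max_t:
            risks.append(None)
            los.append(None)
            his.append(None)
            continue
        s = float(kmf.survival_function_at_times(t).iloc[0])
        risks.append(100 * (1 - s))
        idx = ci.index[ci.index <= t]
        if len(idx):
            row = ci.loc[idx[-1]]
            # survival CI (lo, hi) maps to risk CI (1-hi, 1-lo)
            los.append(100 * (1 - float(row.iloc[1])))
            his.append(100 * (1 - float(row.iloc[0])))
        else:
            los.append(0.0)
            his.append(100.0)
    return KMCurve(list(horizons_years), risks, los, his, kmf)
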