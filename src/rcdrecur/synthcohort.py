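"""Synthetic paired (gold-standard, RCD) cohort generator.

Emulates a two-arm randomised cohort with dense clinic follow-up (19
visits over five years, then five annual visits), piecewise-exponential
recurrence and death hazards calibrated to published trial-side
cumulative risks, an intervention-arm intravenous infusion schedule
(monthly moving to 3–6-monthly over five years, the bisphosphonate
protocol shape), first-year reconstructive-surgery noise, and
configurable coding noise (missed records, coding date lag, unknown-type
degradation, spurious metastasis codes).

Generator truth is the round-trip oracle: with all noise at zero the
recurrence engine must recover the truth record for every woman.

Random-number contract: one root seed; woman ``i`` draws from an
independent substream keyed ``(seed, i)``, so changing ``n_women`` never
shifts the histories of earlier women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Behaviour,
    CodedEvent,
    CodingSystem,
    DeathRecord,
    Intent,
    Laterality,
    OutcomeEvent,
    OutcomeType,
    PatientHistory,
    Source,
    TumourRegistration,
)

__all__ = [
    "SimConfig",
    "NoiseConfig",
    "TruthRecord",
    "RcdTables",
    "piecewise_rates_from_risks",
    "sample_piecewise_exponential",
    "simulate_cohort",
    "emit_rcd",
]

DAYS_PER_YEAR = 365
#: Earliest possible recurrence, in years after diagnosis.  Keeps every
#: generated recurrence clear of the engine's primary-treatment window,
#: which is clinically faithful for an early-stage adjuvant cohort.
ONSET_DELAY_YEARS = 0.75

#: Clinic visit schedule in days after randomisation: quarterly to four
#: years, then six-monthly to five years (19 visits), then five annual
#: visits to ten years.
VISIT_DAYS: tuple[int, ...] = tuple(
    sorted({round(m * 30.4375) for m in range(0, 49, 3)} | {1643, 1826})
    + [365 * y for y in range(6, 11)]
)

#: Intervention-arm infusion days after randomisation: 6 doses every
#: 28 days, 8 every 92, 5 every 183 — 19 doses over five years.
def _infusion_days(start: int = 37) -> tuple[int, ...]:
    days = [start]
    for _ in range(5):
        days.append(days[-1] + 28)
    for _ in range(8):
        days.append(days[-1] + 92)
    for _ in range(5):
        days.append(days[-1] + 183)
    return tuple(days)


INFUSION_DAYS = _infusion_days()
#: Infusions are discontinued this many days before a distant recurrence
#: (treatment stops on clinical suspicion of progression, which precedes
#: the coded metastasis record).
INFUSION_STOP_MARGIN_DAYS = 120


def piecewise_rates_from_risks(
    targets: Sequence[tuple[float, float]], onset_years: float = ONSET_DELAY_YEARS
) -> list[tuple[float, float]]:
    """Solve piecewise-exponential rates hitting cumulative-risk targets.

    ``targets`` is a list of (time in years, cumulative risk in [0, 1))
    pairs with strictly increasing times and risks; the hazard is zero
    before ``onset_years`` and constant within each interval between
    target times.  Returns ``[(end_year, rate per year), ...]`` with the
    last rate extending beyond the final knot.
    """
    pieces: list[tuple[float, float]] = [(onset_years, 0.0)]
    prev_t, prev_s = onset_years, 1.0
    for t, risk in targets:
        if not (0 <= risk < 1):
            raise ValueError(f"risk target {risk} outside [0, 1)")
        s = 1.0 - risk
        if t <= prev_t or s > prev_s:
            raise ValueError("risk targets must be increasing in time and risk")
        rate = math.log(prev_s / s) / (t - prev_t)
        pieces.append((t, rate))
        prev_t, prev_s = t, s
    return pieces


def sample_piecewise_exponential(rng: np.random.Generator, pieces: Sequence[tuple[float, float]]) -> float:
    """Draw one event time (years) by inverting the cumulative hazard."""
    u = rng.random()
    target = -math.log1p(-u)
    cum = 0.0
    prev_t = 0.0
    for end_t, rate in pieces:
        span = end_t - prev_t
        if rate > 0 and cum + rate * span >= target:
            return prev_t + (target - cum) / rate
        cum += rate * span
        prev_t = end_t
    last_rate = pieces[-1][1]
    if last_rate <= 0:
        return math.inf
    return prev_t + (target - cum) / last_rate


@dataclass(frozen=True)
class NoiseConfig:
    """Coding-noise knobs.  All default to zero: the baseline generator
    emulates faithful coding, and noise is switched on explicitly."""

    miss_prob: float = 0.0  # per truth event, evidence never coded
    lag_mean_days: float = 0.0  # gamma coding delay; 0 disables
    lag_sd_days: float = 30.0
    unknown_type_prob: float = 0.0  # recurrence coded only as palliative care
    reconstruction_prob: float = 0.0  # first-year cosmetic surgery record
    spurious_code_prob: float = 0.0  # stray metastasis code, no true event

    def __post_init__(self):
        for name in ("miss_prob", "unknown_type_prob", "reconstruction_prob", "spurious_code_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")


def _default_hazard_targets() -> dict[str, list[tuple[float, float]]]:
    # trial-side cumulative-risk calibration targets at 5 and 10 years
    return {
        "distant": [(5, 0.195), (10, 0.321)],
        "locoregional": [(5, 0.042), (10, 0.057)],
        "contralateral": [(5, 0.009), (10, 0.028)],
        "non_breast_malignancy": [(5, 0.012), (10, 0.027)],
        "other_cause_death": [(5, 0.031), (10, 0.034)],
    }


@dataclass
class SimConfig:
    n_women: int = 2000
    arm_fraction: float = 0.5  # probability of the intervention arm
    accrual_start: Date = Date(2003, 1, 1)
    accrual_end: Date = Date(2006, 12, 31)
    hazard_targets: dict = field(default_factory=_default_hazard_targets)
    onset_delay_years: float = ONSET_DELAY_YEARS
    bc_death_delay_mean_years: float = 1.8  # after distant recurrence
    followup_years: float = 10.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if not (0.0 <= self.arm_fraction <= 1.0):
            raise ValueError("arm_fraction must be a probability")
        # solving the rates validates the targets (raises on decreasing risk)
        self.pieces = {
            k: piecewise_rates_from_risks(v, self.onset_delay_years) if v else [(self.onset_delay_years, 0.0)]
            for k, v in self.hazard_targets.items()
        }


@dataclass
class TruthRecord:
    """Gold-standard truth for one woman (the trial follow-up stand-in)."""

    patient_id: str
    arm: str  # "control" | "intervention"
    randomisation_date: Date
    index_laterality: Laterality
    last_visit_date: Date
    distant_date: Optional[Date] = None
    locoregional_date: Optional[Date] = None
    contralateral_date: Optional[Date] = None
    non_breast_malignancy_date: Optional[Date] = None
    death_date: Optional[Date] = None
    death_cause: Optional[str] = None  # "breast" | "other"

    def gold_events(self) -> list[OutcomeEvent]:
        out = []
        pairs = [
            (self.locoregional_date, OutcomeType.LOCOREGIONAL_RECURRENCE),
            (self.distant_date, OutcomeType.DISTANT_RECURRENCE),
            (self.contralateral_date, OutcomeType.CONTRALATERAL_BREAST_CANCER),
            (self.non_breast_malignancy_date, OutcomeType.NON_BREAST_MALIGNANCY),
        ]
        if self.death_date is not None:
            pairs.append(
                (
                    self.death_date,
                    OutcomeType.BREAST_CANCER_DEATH
                    if self.death_cause == "breast"
                    else OutcomeType.NON_BREAST_CANCER_DEATH,
                )
            )
        for d, outcome in pairs:
            if d is not None:
                out.append(OutcomeEvent(self.patient_id, d, outcome))
        return sorted(out, key=lambda e: e.date)


@dataclass
class RcdTables:
    """The routinely-collected-data side: per-source record lists."""

    registrations: list[TumourRegistration] = field(default_factory=list)
    events: list[CodedEvent] = field(default_factory=list)
    deaths: list[DeathRecord] = field(default_factory=list)

    def histories(self) -> dict[str, PatientHistory]:
        """Group records into per-woman histories (index = first breast
        registration)."""
        regs: dict[str, list[TumourRegistration]] = {}
        for r in self.registrations:
            regs.setdefault(r.patient_id, []).append(r)
        evs: dict[str, list[CodedEvent]] = {}
        for e in self.events:
            evs.setdefault(e.patient_id, []).append(e)
        deaths = {d.patient_id: d for d in self.deaths}
        out: dict[str, PatientHistory] = {}
        for pid, rlist in regs.items():
            rlist = sorted(rlist, key=lambda r: (r.diagnosis_date, r.tumour_id))
            breast = [r for r in rlist if r.site_code.upper().startswith("C50")]
            index = breast[0] if breast else rlist[0]
            others = [r for r in rlist if r is not index]
            out[pid] = PatientHistory(
                patient_id=pid,
                index_registration=index,
                other_registrations=others,
                events=evs.get(pid, []),
                death=deaths.get(pid),
            )
        return out


def _maybe(rng: np.random.Generator, p: float) -> bool:
    return p > 0 and rng.random() < p


def _lag_days(rng: np.random.Generator, noise: NoiseConfig) -> int:
    if noise.lag_mean_days <= 0:
        return 0
    shape = (noise.lag_mean_days / noise.lag_sd_days) ** 2
    scale = noise.lag_sd_days**2 / noise.lag_mean_days
    return int(round(rng.gamma(shape, scale)))


def _simulate_truth(config: SimConfig, i: int, rng: np.random.Generator) -> TruthRecord:
    pid = f"W{i:06d}"
    arm = "intervention" if rng.random() < config.arm_fraction else "control"
    accrual_span = (config.accrual_end - config.accrual_start).days
    rand_date = config.accrual_start + timedelta(days=int(rng.integers(0, accrual_span + 1)))
    laterality = Laterality.LEFT if rng.random() < 0.5 else Laterality.RIGHT

    t = {k: sample_piecewise_exponential(rng, config.pieces[k]) for k in config.pieces}
    bc_death_t = math.inf
    if math.isfinite(t["distant"]):
        bc_death_t = t["distant"] + rng.exponential(config.bc_death_delay_mean_years)
    death_t = min(bc_death_t, t["other_cause_death"])
    horizon = config.followup_years
    end_t = min(death_t, horizon)

    def to_date(years: float) -> Date:
        return rand_date + timedelta(days=int(round(years * DAYS_PER_YEAR)))

    record = TruthRecord(
        patient_id=pid,
        arm=arm,
        randomisation_date=rand_date,
        index_laterality=laterality,
        last_visit_date=rand_date,  # placeholder, set below
    )
    if t["distant"] < end_t:
        record.distant_date = to_date(t["distant"])
    if t["locoregional"] < end_t:
        record.locoregional_date = to_date(t["locoregional"])
    if t["contralateral"] < end_t:
        record.contralateral_date = to_date(t["contralateral"])
    if t["non_breast_malignancy"] < end_t:
        record.non_breast_malignancy_date = to_date(t["non_breast_malignancy"])
    if death_t <= horizon:
        record.death_date = to_date(death_t)
        record.death_cause = "breast" if bc_death_t <= t["other_cause_death"] else "other"

    end_day = int(round(end_t * DAYS_PER_YEAR))
    visit_days = [d for d in VISIT_DAYS if d <= end_day]
    record.last_visit_date = rand_date + timedelta(days=max(visit_days) if visit_days else 0)
    return record


def emit_rcd(
    truth: TruthRecord, config: SimConfig, rng: np.random.Generator
) -> RcdTables:
    """Emit one woman's RCD records from her truth record.

    Zero-noise emissions are constructed so that the recurrence engine's
    first-event output equals the truth exactly; the noise knobs then
    degrade this in the ways coded data degrade in practice.
    """
    noise = config.noise
    tables = RcdTables()
    pid = truth.patient_id
    rand = truth.randomisation_date
    side = truth.index_laterality
    opp = Laterality.RIGHT if side is Laterality.LEFT else Laterality.LEFT
    end_date = truth.death_date or (rand + timedelta(days=int(config.followup_years * DAYS_PER_YEAR)))

    def day(n: int) -> Date:
        return rand + timedelta(days=n)

    def add_event(**kw) -> None:
        ev = CodedEvent(patient_id=pid, **kw)
        if ev.date <= end_date:
            tables.events.append(ev)

    # index registration and primary treatment (both arms)
    tables.registrations.append(
        TumourRegistration(f"{pid}-T0", pid, rand, "C50.9", Behaviour.INVASIVE, side)
    )
    add_event(source=Source.HES, date=day(14), system=CodingSystem.OPCS4, code="B28.3", laterality=side)
    for k in range(6):  # adjuvant chemotherapy, 6 cycles q21d
        add_event(
            source=Source.SACT, date=day(30 + 21 * k), system=CodingSystem.TREATMENT,
            code="CHEMOTHERAPY", intent=Intent.CURATIVE,
        )
    add_event(
        source=Source.RTDS, date=day(200), system=CodingSystem.TREATMENT,
        code="RADIOTHERAPY", intent=Intent.CURATIVE, attributes={"site": "breast"},
    )

    # intervention-arm infusion schedule (single-day systemic attendances)
    if truth.arm == "intervention":
        stop = day(5 * DAYS_PER_YEAR)
        if truth.distant_date is not None:
            stop = min(stop, truth.distant_date - timedelta(days=INFUSION_STOP_MARGIN_DAYS))
        for d in INFUSION_DAYS:
            if day(d) <= stop:
                add_event(
                    source=Source.SACT, date=day(d), system=CodingSystem.TREATMENT,
                    code="CHEMOTHERAPY", intent=Intent.UNKNOWN,
                )

    def emit_recurrence(date: Date, kind: str) -> None:
        if _maybe(rng, noise.miss_prob):
            return
        coded = date + timedelta(days=_lag_days(rng, noise))
        if _maybe(rng, noise.unknown_type_prob):
            add_event(source=Source.HES, date=coded, system=CodingSystem.ICD10, code="Z51.5")
            return
        if kind == "distant":
            site = rng.choice(["C78.0", "C78.7", "C79.3", "C79.5"])
            add_event(source=Source.HES, date=coded, system=CodingSystem.ICD10, code=site)
            add_event(
                source=Source.SACT, date=coded, system=CodingSystem.TREATMENT,
                code="CHEMOTHERAPY", intent=Intent.PALLIATIVE,
                attributes={"duration_days": "3"},
            )
        elif kind == "locoregional":
            add_event(source=Source.HES, date=coded, system=CodingSystem.ICD10, code="C77.3", laterality=side)
            add_event(source=Source.HES, date=coded, system=CodingSystem.OPCS4, code="B28.1", laterality=side)
        elif kind == "contralateral":
            tables.registrations.append(
                TumourRegistration(f"{pid}-TC", pid, coded, "C50.4", Behaviour.INVASIVE, opp)
            )
        elif kind == "non_breast_malignancy":
            tables.registrations.append(
                TumourRegistration(f"{pid}-TN", pid, coded, "C34.1", Behaviour.INVASIVE, Laterality.UNKNOWN)
            )

    if truth.distant_date is not None:
        emit_recurrence(truth.distant_date, "distant")
    if truth.locoregional_date is not None:
        emit_recurrence(truth.locoregional_date, "locoregional")
    if truth.contralateral_date is not None:
        emit_recurrence(truth.contralateral_date, "contralateral")
    if truth.non_breast_malignancy_date is not None:
        emit_recurrence(truth.non_breast_malignancy_date, "non_breast_malignancy")

    # first-year reconstructive / oncoplastic surgery noise
    if _maybe(rng, noise.reconstruction_prob):
        d = int(rng.integers(285, DAYS_PER_YEAR))
        lat = side if rng.random() < 0.5 else opp
        code = rng.choice(["B29.1", "B30.1", "B31.2"])
        add_event(source=Source.HES, date=day(d), system=CodingSystem.OPCS4, code=code, laterality=lat)

    # spurious stray metastasis code
    if _maybe(rng, noise.spurious_code_prob):
        span = (min(end_date, rand + timedelta(days=int(config.followup_years * DAYS_PER_YEAR))) - rand).days
        if span > 285:
            d = int(rng.integers(285, span))
            add_event(source=Source.HES, date=day(d), system=CodingSystem.ICD10, code="C78.1")

    if truth.death_date is not None:
        cause = "C50.9" if truth.death_cause == "breast" else "I21.9"
        tables.deaths.append(DeathRecord(pid, truth.death_date, cause))
    return tables


def simulate_cohort(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> tuple[list[TruthRecord], RcdTables]:
    """Generate the paired cohort: truth records and RCD tables."""
    config = config or SimConfig()
    root = config.seed if seed is None else seed
    truths: list[TruthRecord] = []
    tables = RcdTables()
    for i in range(config.n_women):
        rng = np.random.default_rng([root, i])
        truth = _simulate_truth(config, i, rng)
        truths.append(truth)
        t = emit_rcd(truth, config, rng)
        tables.registrations.extend(t.registrations)
        tables.events.extend(t.events)
        tables.deaths.extend(t.deaths)
    return truths, tables
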