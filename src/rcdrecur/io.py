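"""Readers, writers and configuration for the command-line pipeline.

All tables are comma-separated UTF-8 CSV with ISO-8601 dates; the empty
string means missing.  One events table per RCD source, plus a
registrations table, a deaths table and (for validation) a gold-standard
follow-up table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import date as Date
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .engine import EngineConfig
from .model import (
    Behaviour,
    CodeConfig,
    CodedEvent,
    CodeRole,
    CodeSet,
    CodingSystem,
    DeathRecord,
    Intent,
    Laterality,
    OutcomeEvent,
    OutcomeType,
    PatientHistory,
    PriorityOrder,
    Source,
    TumourRegistration,
)
from .synthcohort import RcdTables, TruthRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "DataError",
    "load_sources",
    "write_rcd_tables",
    "write_gold",
    "read_gold",
    "write_events",
    "read_events",
    "engine_config_from_yaml",
    "report",
]

MAX_MALFORMED_FRACTION = 0.01

EVENT_COLUMNS = ["patient_id", "source", "date", "system", "code", "laterality", "intent", "attributes"]
REGISTRATION_COLUMNS = ["tumour_id", "patient_id", "diagnosis_date", "site_code", "behaviour", "laterality", "provisional"]
DEATH_COLUMNS = ["patient_id", "death_date", "underlying_cause", "mentioned_causes"]
GOLD_COLUMNS = ["patient_id", "arm", "randomisation_date", "last_visit_date", "event_type", "event_date"]
OUTCOME_COLUMNS = ["patient_id", "date", "outcome", "rule_id", "evidence_refs"]


class SchemaError(Exception):
    """A file does not match its expected schema."""


class DataError(Exception):
    """Too many malformed rows, or otherwise unusable data."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_date(value) -> Date:
    return Date.fromisoformat(str(value))


def _checked(df: pd.DataFrame, path, parser):
    """Parse rows, logging malformed ones; abort when >1% fail."""
    good, bad = [], 0
    for _, row in df.iterrows():
        try:
            good.append(parser(row))
        except (ValueError, KeyError) as exc:
            bad += 1
            logger.warning("%s: malformed row skipped (%s)", path, exc)
    if len(df) and bad / len(df) > MAX_MALFORMED_FRACTION:
        raise DataError(f"{path}: {bad}/{len(df)} malformed rows (> {MAX_MALFORMED_FRACTION:.0%})")
    return good


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_registrations(path) -> list[TumourRegistration]:
    df = _read_csv(path)
    _require_columns(df, REGISTRATION_COLUMNS, path)

    def parse(row):
        return TumourRegistration(
            tumour_id=row["tumour_id"],
            patient_id=row["patient_id"],
            diagnosis_date=_parse_date(row["diagnosis_date"]),
            site_code=row["site_code"],
            behaviour=Behaviour[row["behaviour"] or "INVASIVE"],
            laterality=Laterality[row["laterality"] or "UNKNOWN"],
            provisional=row["provisional"].lower() in ("true", "1", "yes"),
        )

    return _checked(df, path, parse)


def read_deaths(path) -> list[DeathRecord]:
    df = _read_csv(path)
    _require_columns(df, DEATH_COLUMNS, path)

    def parse(row):
        mentioned = tuple(c for c in row["mentioned_causes"].split(";") if c)
        return DeathRecord(
            patient_id=row["patient_id"],
            death_date=_parse_date(row["death_date"]),
            underlying_cause=row["underlying_cause"],
            mentioned_causes=mentioned,
        )

    return _checked(df, path, parse)


def read_source_events(path) -> list[CodedEvent]:
    df = _read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)

    def parse(row):
        return CodedEvent(
            patient_id=row["patient_id"],
            source=Source[row["source"]],
            date=_parse_date(row["date"]),
            system=CodingSystem[row["system"]],
            code=row["code"],
            laterality=Laterality[row["laterality"] or "UNKNOWN"],
            intent=Intent[row["intent"] or "UNKNOWN"],
            attributes=json.loads(row["attributes"]) if row["attributes"] else {},
        )

    return _checked(df, path, parse)


def load_sources(
    registrations_path,
    deaths_path=None,
    event_paths: Sequence = (),
) -> dict[str, PatientHistory]:
    """Read the source tables and group them into per-woman histories.

    The index registration is the woman's earliest breast-primary
    registration; women with no breast registration are skipped with a
    warning.
    """
    registrations = read_registrations(registrations_path)
    deaths = read_deaths(deaths_path) if deaths_path else []
    events: list[CodedEvent] = []
    for p in event_paths:
        events.extend(read_source_events(p))
    tables = RcdTables(registrations=registrations, events=events, deaths=deaths)
    histories = {}
    config = CodeConfig()
    for pid, hist in tables.histories().items():
        from .model import classify_diagnosis_code

        try:
            role = classify_diagnosis_code(hist.index_registration.site_code, config)
        except ValueError:
            role = CodeRole.NON_MALIGNANT
        if role is not CodeRole.BREAST_PRIMARY:
            logger.warning("patient %s: no breast-primary registration, skipped", pid)
            continue
        histories[pid] = hist
    return histories


# ---------------------------------------------------------------------------
# writers


def _date_str(d: Optional[Date]) -> str:
    return d.isoformat() if d is not None else ""


def write_rcd_tables(tables: RcdTables, outdir) -> dict[str, Path]:
    """Write registrations, deaths and one events CSV per source."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    reg_rows = [
        {
            "tumour_id": r.tumour_id,
            "patient_id": r.patient_id,
            "diagnosis_date": r.diagnosis_date.isoformat(),
            "site_code": r.site_code,
            "behaviour": r.behaviour.value,
            "laterality": r.laterality.value,
            "provisional": str(r.provisional).lower(),
        }
        for r in tables.registrations
    ]
    paths["registrations"] = outdir / "registrations.csv"
    pd.DataFrame(reg_rows, columns=REGISTRATION_COLUMNS).to_csv(paths["registrations"], index=False)

    death_rows = [
        {
            "patient_id": d.patient_id,
            "death_date": d.death_date.isoformat(),
            "underlying_cause": d.underlying_cause,
            "mentioned_causes": ";".join(d.mentioned_causes),
        }
        for d in tables.deaths
    ]
    paths["deaths"] = outdir / "deaths.csv"
    pd.DataFrame(death_rows, columns=DEATH_COLUMNS).to_csv(paths["deaths"], index=False)

    for source in Source:
        rows = [
            {
                "patient_id": e.patient_id,
                "source": e.source.value,
                "date": e.date.isoformat(),
                "system": e.system.value,
                "code": e.code,
                "laterality": e.laterality.value,
                "intent": e.intent.value,
                "attributes": json.dumps(dict(e.attributes), sort_keys=True) if e.attributes else "",
            }
            for e in tables.events
            if e.source is source
        ]
        key = f"events_{source.value.lower()}"
        paths[key] = outdir / f"{key}.csv"
        pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(paths[key], index=False)
    return paths


def write_gold(truths: Sequence[TruthRecord], path) -> Path:
    """One row per gold event; women with no events get a blank-event row."""
    path = Path(path)
    rows = []
    for t in truths:
        base = {
            "patient_id": t.patient_id,
            "arm": t.arm,
            "randomisation_date": t.randomisation_date.isoformat(),
            "last_visit_date": t.last_visit_date.isoformat(),
        }
        events = t.gold_events()
        if not events:
            rows.append({**base, "event_type": "", "event_date": ""})
        for ev in events:
            rows.append({**base, "event_type": ev.outcome.value, "event_date": ev.date.isoformat()})
    pd.DataFrame(rows, columns=GOLD_COLUMNS).to_csv(path, index=False)
    return path


def read_gold(path):
    """Returns (windows info, events): patient -> (arm, randomisation,
    last_visit) and patient -> list of OutcomeEvent."""
    df = _read_csv(path)
    _require_columns(df, GOLD_COLUMNS, path)
    info: dict[str, tuple] = {}
    events: dict[str, list[OutcomeEvent]] = {}

    def parse(row):
        pid = row["patient_id"]
        info[pid] = (
            row["arm"],
            _parse_date(row["randomisation_date"]),
            _parse_date(row["last_visit_date"]),
        )
        events.setdefault(pid, [])
        if row["event_type"]:
            events[pid].append(
                OutcomeEvent(pid, _parse_date(row["event_date"]), OutcomeType[row["event_type"]])
            )
        return pid

    _checked(df, path, parse)
    return info, events


def write_events(results, path) -> Path:
    """Write engine output (per-woman AlgorithmResult) to an events CSV."""
    rows = []
    for res in results:
        for cand in res.events:
            refs = ";".join(_evidence_ref(ev) for ev in cand.evidence)
            rows.append(
                {
                    "patient_id": cand.patient_id,
                    "date": cand.date.isoformat(),
                    "outcome": cand.outcome.value,
                    "rule_id": cand.rule_id,
                    "evidence_refs": refs,
                }
            )
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False)
    return Path(path)


def _evidence_ref(ev) -> str:
    if isinstance(ev, CodedEvent):
        return f"{ev.source.value}:{ev.date.isoformat()}:{ev.code}"
    if isinstance(ev, TumourRegistration):
        return f"REG:{ev.diagnosis_date.isoformat()}:{ev.tumour_id}"
    return f"DEATH:{ev.death_date.isoformat()}"


def read_events(path) -> dict[str, list[OutcomeEvent]]:
    df = _read_csv(path)
    _require_columns(df, OUTCOME_COLUMNS, path)
    out: dict[str, list[OutcomeEvent]] = {}

    def parse(row):
        ev = OutcomeEvent(row["patient_id"], _parse_date(row["date"]), OutcomeType[row["outcome"]])
        out.setdefault(ev.patient_id, []).append(ev)
        return ev

    _checked(df, path, parse)
    return out


# ---------------------------------------------------------------------------
# configuration


def engine_config_from_yaml(path) -> EngineConfig:
    """Build an EngineConfig from a YAML file; absent keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "code_lists" in raw:
        sets = {
            CodeRole[role.upper()]: CodeSet(role, frozenset(prefixes))
            for role, prefixes in raw["code_lists"].items()
        }
        kwargs["codes"] = CodeConfig(sets)
    for key in (
        "primary_treatment_window_days",
        "infusion_min_count",
        "infusion_min_gap_days",
        "infusion_max_gap_days",
        "adjustment_flag",
        "reconstruction_filter_enabled",
        "infusion_filter_enabled",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "reconstruction_codes" in raw:
        kwargs["reconstruction_codes"] = CodeSet("reconstruction", frozenset(raw["reconstruction_codes"]))
    if "resection_codes" in raw:
        kwargs["resection_codes"] = CodeSet("breast_resection", frozenset(raw["resection_codes"]))
    if "priority" in raw:
        kwargs["priority"] = PriorityOrder([OutcomeType[x] for x in raw["priority"]])
    try:
        return EngineConfig(**kwargs)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid engine configuration ({exc})") from exc


# ---------------------------------------------------------------------------
# reporting


def _fmt(est) -> str:
    v, lo, hi = est.round1()
    if v is None:
        return "undefined"
    return f"{v:.1f} ({lo:.1f}, {hi:.1f})"


def report(validation, outdir) -> dict[str, Path]:
    """Write agreement, metrics, crosstab and KM CSVs plus a text summary.

    The agreement CSV mirrors the published table layout: the event
    cross-classification block, the censored-before-period block, the
    date-difference block, and all-time vs within-window performance.
    """
    from .metrics import PairClassLabel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    agreement_rows, metric_rows = [], []
    for (name, lm), block in sorted(
        validation.blocks.items(), key=lambda kv: (kv[0][0], kv[0][1] is not None, kv[0][1] or 0)
    ):
        label = f"{name}" + (f"@{lm}y" if lm else "")
        t = block.table
        agreement_rows.append(
            {
                "analysis": label,
                "event_both": t[PairClassLabel.EVENT_BOTH],
                "event_trial_only": t[PairClassLabel.EVENT_TRIAL_ONLY],
                "event_rcd_only": t[PairClassLabel.EVENT_RCD_ONLY],
                "no_event_either": t[PairClassLabel.NO_EVENT_EITHER],
                "censored_trial_only": t[PairClassLabel.CENSORED_TRIAL_ONLY],
                "censored_rcd_only": t[PairClassLabel.CENSORED_RCD_ONLY],
                "censored_both": t[PairClassLabel.CENSORED_BOTH],
                "diff_lt6m": int(block.date_bins.loc["<6 months", "count"]),
                "diff_6_12m": int(block.date_bins.loc["6-12 months", "count"]),
                "diff_gt1y": int(block.date_bins.loc[">1 year", "count"]),
            }
        )
        for period, perf in (("all", block.perf), ("within_6m", block.perf_within_window)):
            metric_rows.append(
                {
                    "analysis": label,
                    "match": period,
                    "sensitivity": _fmt(perf.sensitivity),
                    "specificity": _fmt(perf.specificity),
                    "ppv": _fmt(perf.ppv),
                    "npv": _fmt(perf.npv),
                }
            )
    paths["agreement"] = outdir / "agreement.csv"
    pd.DataFrame(agreement_rows).to_csv(paths["agreement"], index=False)
    paths["metrics"] = outdir / "metrics.csv"
    pd.DataFrame(metric_rows).to_csv(paths["metrics"], index=False)

    if validation.crosstab is not None:
        paths["crosstab"] = outdir / "crosstab.csv"
        validation.crosstab.to_csv(paths["crosstab"])

    km_rows = []
    for (name, side), curve in sorted(validation.km.items()):
        for h, r, lo, hi in zip(curve.horizons, curve.risk, curve.lower, curve.upper):
            km_rows.append(
                {
                    "analysis": name,
                    "side": side,
                    "horizon_years": h,
                    "cumulative_risk_pct": round(r, 1) if r is not None else "",
                    "ci_lower": round(lo, 1) if lo is not None else "",
                    "ci_upper": round(hi, 1) if hi is not None else "",
                }
            )
    paths["km"] = outdir / "km.csv"
    pd.DataFrame(km_rows, columns=["analysis", "side", "horizon_years", "cumulative_risk_pct", "ci_lower", "ci_upper"]).to_csv(paths["km"], index=False)

    lines = ["Validation summary", "=================="]
    for row in metric_rows:
        lines.append(
            f"{row['analysis']} [{row['match']}]: sens {row['sensitivity']}, "
            f"spec {row['specificity']}, ppv {row['ppv']}, npv {row['npv']}"
        )
    if validation.compatibility:
        lines.append("")
        lines.append("First-event compatibility (%):")
        for k, v in validation.compatibility.items():
            lines.append(f"  {k}: {v:.1f}")
    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
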