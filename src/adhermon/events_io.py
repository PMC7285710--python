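"""Domain types, file formats and validation for pill-box adherence monitoring.

The monitoring pipeline revolves around a handful of small records:

* :class:`PrescriptionSchedule` — the fixed twice-daily dosing plan
  (clock times, target interval, allowed intake window, interval margin)
  together with the alarm-escalation parameters.
* :class:`IntakeEvent` — one pill-box opening: who, when, which drug,
  how many pills.
* :class:`DoseSlot` — one scheduled dosing occasion and its resolved
  status after matching intakes to the schedule.
* :class:`FeedbackEvent` — one generated alarm/text message.
* :class:`PatientRecord` — a patient's arm assignment, event log,
  per-visit drug trough levels and clinical-event flags.

All timestamps are timezone-naive local clock time; days are calendar
days of the local clock.  File formats are plain CSV (UTF-8, ISO 8601
timestamps) plus a YAML config; see the read/write functions below.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "PrescriptionSchedule",
    "IntakeEvent",
    "DoseSlot",
    "FeedbackEvent",
    "PatientRecord",
    "Settings",
    "read_event_log",
    "write_event_log",
    "read_cohort",
    "write_cohort",
    "read_troughs",
    "write_troughs",
    "read_config",
    "write_report",
    "assemble_records",
]

N_VISITS = 6
DAYS_PER_PERIOD = 28  # follow-up visits at 4, 8, 12, 16, 20, 24 weeks


class ValidationError(ValueError):
    """Raised when an input file or parameter set violates an invariant."""


def _parse_clock(value: Any) -> dt.time:
    if isinstance(value, dt.time):
        return value
    if isinstance(value, str):
        try:
            hh, mm = value.split(":")
            return dt.time(int(hh), int(mm))
        except Exception as exc:  # noqa: BLE001
            raise ValidationError(f"bad clock time {value!r} (expected HH:MM)") from exc
    raise ValidationError(f"bad clock time {value!r}")


@dataclass(frozen=True)
class PrescriptionSchedule:
    """Fixed daily dosing plan and feedback parameters.

    Parameters
    ----------
    dose_times:
        Scheduled clock times, strictly increasing within the day.
        Default 08:00 and 20:00 (twice daily, 12 h apart).
    target_interval_h:
        Prescribed between-dose interval in hours (default 12).
    pills_per_dose:
        Pills per scheduled dose (default 1).
    window_h:
        Half-width of the allowed intake window around each scheduled
        time, hours (default 3, i.e. a ±3 h window).
    interval_margin:
        Fractional margin on the target interval defining a "correct"
        dosing interval (default 0.25, i.e. 9–15 h for a 12 h target).
    escalation_gap_min:
        Minutes between consecutive missed-dose reminder texts (30).
    max_escalations:
        Number of additional reminders after the first alarm (2).
    alarm_latency_min:
        Delivery latency of alarms after the triggering instant.
        Modeled as 0 by default: alarms fire exactly at the window break.
    """

    dose_times: tuple[dt.time, ...] = (dt.time(8, 0), dt.time(20, 0))
    target_interval_h: float = 12.0
    pills_per_dose: int = 1
    window_h: float = 3.0
    interval_margin: float = 0.25
    escalation_gap_min: float = 30.0
    max_escalations: int = 2
    alarm_latency_min: float = 0.0

    def __post_init__(self) -> None:
        times = tuple(_parse_clock(t) for t in self.dose_times)
        object.__setattr__(self, "dose_times", times)
        if not times:
            raise ValidationError("schedule needs at least one dose time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("dose_times must be strictly increasing within a day")
        if self.window_h <= 0:
            raise ValidationError("window_h must be positive")
        if not 0 < self.interval_margin < 1:
            raise ValidationError("interval_margin must lie in (0, 1)")
        if self.pills_per_dose < 1:
            raise ValidationError("pills_per_dose must be a positive integer")
        if self.max_escalations < 0:
            raise ValidationError("max_escalations must be >= 0")
        if self.target_interval_h <= 0:
            raise ValidationError("target_interval_h must be positive")
        if len(times) == 2:
            gap = (
                dt.datetime.combine(dt.date.min, times[1])
                - dt.datetime.combine(dt.date.min, times[0])
            ).total_seconds() / 3600.0
            if abs(gap - self.target_interval_h) > 1e-9:
                raise ValidationError(
                    f"dose times {gap:g} h apart but target interval is "
                    f"{self.target_interval_h:g} h"
                )

    @property
    def doses_per_day(self) -> int:
        return len(self.dose_times)

    @property
    def window(self) -> dt.timedelta:
        return dt.timedelta(hours=self.window_h)

    @property
    def escalation_gap(self) -> dt.timedelta:
        return dt.timedelta(minutes=self.escalation_gap_min)

    def slot_times(self, start: dt.date, days: int) -> list[dt.datetime]:
        """All scheduled dosing datetimes for ``days`` days from ``start``.

        Slot index is 0-based from the first scheduled dose on the start
        date: ``index = day_offset * doses_per_day + position_in_day``.
        """
        return [
            dt.datetime.combine(start + dt.timedelta(days=d), t)
            for d in range(days)
            for t in self.dose_times
        ]


@dataclass(frozen=True, order=True)
class IntakeEvent:
    """One recorded pill-box opening."""

    patient_id: str = field(compare=False)
    timestamp: dt.datetime = field(compare=True)
    pills_taken: int = field(compare=False)
    drug_id: str = field(compare=False, default="immunosuppressant")
    order: int = field(compare=True, default=0)  # file order, breaks timestamp ties

    def __post_init__(self) -> None:
        if self.pills_taken < 1:
            raise ValidationError("a recorded opening must have pills_taken >= 1")


@dataclass
class DoseSlot:
    """One scheduled dosing occasion with its resolved status."""

    patient_id: str
    scheduled: dt.datetime
    slot_index: int
    status: str = "missed"  # taken_ok | taken_dosage_error | taken_out_of_window | missed
    matched_event: IntakeEvent | None = None

    STATUSES = ("taken_ok", "taken_dosage_error", "taken_out_of_window", "missed")

    def __post_init__(self) -> None:
        if self.status not in self.STATUSES:
            raise ValidationError(f"unknown slot status {self.status!r}")
        if (self.status == "missed") != (self.matched_event is None):
            raise ValidationError("status 'missed' iff no matched event")


@dataclass(frozen=True)
class FeedbackEvent:
    """One generated alarm/text message."""

    patient_id: str
    timestamp: dt.datetime
    kind: str  # missed_dose | dosage_error | timing_error
    escalation_index: int
    slot_index: int

    KINDS = ("missed_dose", "dosage_error", "timing_error")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown feedback kind {self.kind!r}")
        if self.escalation_index and self.kind != "missed_dose":
            raise ValidationError("only missed_dose feedback escalates")


@dataclass
class PatientRecord:
    """Everything the analysis needs to know about one patient."""

    patient_id: str
    arm: str  # intervention | control
    start_date: dt.date
    schedule: PrescriptionSchedule = field(default_factory=PrescriptionSchedule)
    events: list[IntakeEvent] = field(default_factory=list)
    troughs: dict[int, dict[str, float]] = field(default_factory=dict)
    clinical_events: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "control"):
            raise ValidationError(f"unknown arm {self.arm!r}")
        bad = [v for v in self.troughs if not 1 <= v <= N_VISITS]
        if bad:
            raise ValidationError(f"trough visit indices must be 1..{N_VISITS}, got {bad}")

    def period_range(self, period_index: int) -> tuple[dt.date, dt.date]:
        """Half-open [start, end) calendar window of a 4-week follow-up period."""
        if not 1 <= period_index <= N_VISITS:
            raise ValidationError(f"period_index must be 1..{N_VISITS}")
        start = self.start_date + dt.timedelta(days=DAYS_PER_PERIOD * (period_index - 1))
        return start, start + dt.timedelta(days=DAYS_PER_PERIOD)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["patient_id", "timestamp", "drug_id", "pills_taken"]


def read_event_log(path: str | Path) -> list[IntakeEvent]:
    """Read an intake-event CSV and return validated, per-patient sorted events.

    The file must have a header ``patient_id,timestamp,drug_id,pills_taken``.
    Timestamps are ISO 8601, timezone-naive. Rows with 0 pills, malformed
    timestamps or unknown columns raise :class:`ValidationError` naming the
    offending line. Events are returned sorted by (patient, timestamp) with
    ties preserving file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"{path}: unreadable CSV: {exc}") from exc
    if list(df.columns) != EVENT_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {EVENT_COLUMNS}, found {list(df.columns)}"
        )
    events: list[IntakeEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is header
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp))
        except ValueError as exc:
            raise ValidationError(f"{path}:{i}: malformed timestamp {row.timestamp!r}") from exc
        if ts.tzinfo is not None:
            raise ValidationError(f"{path}:{i}: timestamps must be timezone-naive")
        try:
            pills = int(row.pills_taken)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{i}: bad pill count {row.pills_taken!r}") from exc
        if pills < 1:
            raise ValidationError(f"{path}:{i}: pills_taken must be >= 1, got {pills}")
        events.append(
            IntakeEvent(
                patient_id=str(row.patient_id),
                timestamp=ts,
                pills_taken=pills,
                drug_id=str(row.drug_id),
                order=i,
            )
        )
    events.sort(key=lambda e: (e.patient_id, e.timestamp, e.order))
    return events


def write_event_log(events: Sequence[IntakeEvent], path: str | Path) -> None:
    """Write events to the CSV event-log format (inverse of :func:`read_event_log`)."""
    df = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "timestamp": [e.timestamp.isoformat() for e in events],
            "drug_id": [e.drug_id for e in events],
            "pills_taken": [e.pills_taken for e in events],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read cohort metadata CSV: ``patient_id,arm,start_date`` plus optional
    0/1 clinical-event columns."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "arm", "start_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: cohort file missing columns {sorted(missing)}")
    bad = set(df["arm"]) - {"intervention", "control"}
    if bad:
        raise ValidationError(f"{path}: unknown arm values {sorted(bad)}")
    df["start_date"] = pd.to_datetime(df["start_date"]).dt.date
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_troughs(path: str | Path) -> pd.DataFrame:
    """Read trough-level CSV: ``patient_id,visit,drug_id,level``."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "visit", "drug_id", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: trough file missing columns {sorted(missing)}")
    if ((df["visit"] < 1) | (df["visit"] > N_VISITS)).any():
        raise ValidationError(f"{path}: visit indices must be 1..{N_VISITS}")
    if (df["level"] <= 0).any():
        raise ValidationError(f"{path}: trough levels must be positive")
    return df


def write_troughs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def assemble_records(
    cohort: pd.DataFrame,
    events: Sequence[IntakeEvent] = (),
    troughs: pd.DataFrame | None = None,
    schedule: PrescriptionSchedule | None = None,
) -> list[PatientRecord]:
    """Join cohort metadata, an event log and trough levels into records.

    Extra 0/1 columns in the cohort table beyond
    ``patient_id,arm,start_date`` are treated as clinical-event flags.
    """
    schedule = schedule or PrescriptionSchedule()
    by_patient: dict[str, list[IntakeEvent]] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)
    trough_map: dict[str, dict[int, dict[str, float]]] = {}
    if troughs is not None:
        for row in troughs.itertuples(index=False):
            trough_map.setdefault(str(row.patient_id), {}).setdefault(int(row.visit), {})[
                str(row.drug_id)
            ] = float(row.level)
    clinical_cols = [c for c in cohort.columns if c not in ("patient_id", "arm", "start_date")]
    records = []
    for row in cohort.itertuples(index=False):
        pid = str(row.patient_id)
        start = row.start_date
        if not isinstance(start, dt.date):
            start = pd.to_datetime(start).date()
        records.append(
            PatientRecord(
                patient_id=pid,
                arm=str(row.arm),
                start_date=start,
                schedule=schedule,
                events=sorted(
                    by_patient.get(pid, []), key=lambda e: (e.timestamp, e.order)
                ),
                troughs=trough_map.get(pid, {}),
                clinical_events={c: bool(getattr(row, c)) for c in clinical_cols},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class Settings:
    """Fully populated schedule + simulation + analysis settings."""

    schedule: PrescriptionSchedule
    simulation: dict[str, Any]
    analysis: dict[str, Any]


_SCHEDULE_KEYS = {f.name for f in dataclasses.fields(PrescriptionSchedule)}


def read_config(path: str | Path | None = None) -> Settings:
    """Load a YAML/JSON config; unset fields fall back to the trial defaults.

    Defaults: twice-daily dosing at 08:00/20:00 with a 12 h target interval,
    a ±3 h intake window, a ±25 % interval margin, and missed-dose alarms
    escalating up to twice at 30 min intervals.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
    sched_raw = dict(raw.get("schedule") or {})
    unknown = set(sched_raw) - _SCHEDULE_KEYS
    if unknown:
        raise ValidationError(f"unknown schedule keys {sorted(unknown)}")
    schedule = PrescriptionSchedule(**sched_raw)
    return Settings(
        schedule=schedule,
        simulation=dict(raw.get("simulation") or {}),
        analysis=dict(raw.get("analysis") or {}),
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(result: "TrialResult", path: str | Path) -> None:  # noqa: F821
    """Write a trial result as JSON (``<path>``) and TSV (``<path>.tsv``).

    The tables mirror the arm-comparison layout of a trial report:
    per-outcome rows with mean ± SD per group and a p-value, and
    event-count rows with counts, percentages and a p-value.
    """
    d = result.to_dict()
    if not d.get("n_a") and not d.get("n_b"):
        raise ValidationError("no patients: refusing to write an empty report")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(d), fh, indent=2)
        fh.write("\n")
    lines = [
        "# No multiplicity adjustment applied; each outcome tested at alpha = 0.05.",
        f"outcome\t{d['group_a']} (n={d['n_a']})\t{d['group_b']} (n={d['n_b']})\tp\tmethod",
    ]
    for row in d["rows"]:
        a = f"{row['mean_a']:.2f} ± {row['sd_a']:.2f}" if row["mean_a"] is not None else "–"
        b = f"{row['mean_b']:.2f} ± {row['sd_b']:.2f}" if row["mean_b"] is not None else "–"
        p = "–" if row["p"] is None else f"{row['p']:.3f}"
        lines.append(f"{row['outcome']}\t{a}\t{b}\t{p}\t{row['method']}")
    for row in d["event_rows"]:
        a = f"{row['count_a']} ({row['pct_a']:.1f}%)"
        b = f"{row['count_b']} ({row['pct_b']:.1f}%)"
        p = "–" if row["p"] is None else f"{row['p']:.3f}"
        lines.append(f"{row['outcome']}\t{a}\t{b}\t{p}\t{row['method']}")
    Path(str(path) + ".tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
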