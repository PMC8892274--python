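"""Alert event data model, validation, and CSV interchange.

An event log is one row per alert instance: which physician saw which
patient's alert, when, what they did (dismiss / acknowledge / remove the
catheter order), how long they took, and the clinical/contextual
attributes carried as covariates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

ACTIONS = ("dismiss", "acknowledge", "remove_order")
RANKS = ("intern", "resident", "fellow", "attending")
GENDERS = ("F", "M")

#: canonical column order of the CSV interchange format
COLUMNS = [
    "alert_id",
    "physician_id",
    "patient_id",
    "timestamp",
    "action",
    "processing_time",
    "ward_round",
    "physician_rank",
    "specialty",
    "department",
    "patient_age",
    "patient_gender",
    "patient_race",
    "length_of_stay",
    "diagnosis_count",
]

_STRING_COLUMNS = [
    "alert_id", "physician_id", "patient_id", "action", "physician_rank",
    "specialty", "department", "patient_gender", "patient_race",
]
_INT_COLUMNS = ["patient_age", "length_of_stay", "diagnosis_count"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong shape."""


class RowValidationError(ValueError):
    """A row holds an unparseable or out-of-domain value."""


@dataclass
class EventLog:
    """Ordered collection of alert events plus free-text provenance.

    ``events`` is a DataFrame with the :data:`COLUMNS` schema;
    ``provenance`` records where the log came from (file path, or the
    generating seed for synthetic logs).
    """

    events: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def sorted(self) -> "EventLog":
        """Deterministic (physician_id, timestamp, alert_id) ordering.

        Ties in timestamp within a physician are broken lexicographically
        by alert_id so that the habit update has a total order.
        """
        df = self.events.sort_values(
            ["physician_id", "timestamp", "alert_id"], kind="mergesort"
        ).reset_index(drop=True)
        return EventLog(df, dict(self.provenance))


@dataclass
class ValidationReport:
    valid: bool
    violations: dict[str, list[str]]  # invariant name -> offending alert_ids

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.valid:
            return "EventLog valid: no violations"
        lines = [f"EventLog invalid: {sum(map(len, self.violations.values()))} violations"]
        for name, ids in self.violations.items():
            lines.append(f"  {name}: {len(ids)} rows (e.g. {ids[:5]})")
        return "\n".join(lines)


def _load_column_map(column_map: Mapping[str, str] | str | Path | None) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise SchemaError("column-mapping YAML must hold a flat mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    return dict(column_map)


def read_event_log(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> EventLog:
    """Read an alert event log from CSV.

    Parameters
    ----------
    path
        CSV file with a header row and the canonical columns.
    column_map
        Optional mapping (dict, or path to a YAML file) from the column
        names used in the source file to the canonical names, for EMR
        exports with different headers, e.g. ``{"doctor": "physician_id"}``.

    Raises
    ------
    SchemaError
        if a required column is absent.
    RowValidationError
        if a timestamp fails to parse or a processing time is negative,
        citing the offending row index.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLUMNS})
    mapping = _load_column_map(column_map)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()
    for col in _STRING_COLUMNS:
        df[col] = df[col].astype("string").astype(object)

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad_ts = ts.isna() & df["timestamp"].notna()
    if bad_ts.any() or ts.isna().any():
        row = int(ts.isna().idxmax())
        raise RowValidationError(
            f"row {row}: unparseable timestamp {df['timestamp'].iloc[row]!r}"
        )
    df["timestamp"] = ts

    pt = pd.to_numeric(df["processing_time"], errors="coerce")
    if pt.isna().any():
        row = int(pt.isna().idxmax())
        raise RowValidationError(f"row {row}: unparseable processing_time")
    if (pt < 0).any():
        row = int((pt < 0).idxmax())
        raise RowValidationError(
            f"row {row}: negative processing_time {pt.iloc[row]}"
        )
    df["processing_time"] = pt.astype(float)

    if df["ward_round"].dtype != bool:
        df["ward_round"] = (
            df["ward_round"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df["ward_round"].isna().any():
            row = int(df["ward_round"].isna().idxmax())
            raise RowValidationError(f"row {row}: unparseable ward_round")
        df["ward_round"] = df["ward_round"].astype(bool)
    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise RowValidationError(f"row {row}: unparseable {col}")
        df[col] = df[col].astype(int)

    return EventLog(df, provenance={"source": str(path), "n_events": len(df)})


def write_event_log(log: EventLog, path: str | Path) -> Path:
    """Write a log to CSV (UTF-8, ISO-8601 timestamps); returns the path.

    Round-trip safe: ``read_event_log(write_event_log(log, p))`` reproduces
    the log field for field (processing times are written at full precision).
    """
    path = Path(path)
    df = log.events.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["ward_round"] = df["ward_round"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, columns=COLUMNS, encoding="utf-8")
    return path


def validate(log: EventLog) -> ValidationReport:
    """Check every event-log invariant; violations are data, not exceptions.

    The report lists, per invariant, the offending alert_ids.
    """
    df = log.events
    violations: dict[str, list[str]] = {}

    def flag(name: str, mask) -> None:
        if mask.any():
            violations[name] = df.loc[mask, "alert_id"].astype(str).tolist()

    flag("duplicate_alert_id", df["alert_id"].duplicated(keep=False))
    pt = pd.to_numeric(df["processing_time"], errors="coerce")
    flag("processing_time_nonnegative_finite", ~(pt.notna() & (pt >= 0) & pt.apply(pd.api.types.is_number) & (pt.abs() != float("inf"))))
    flag("action_enum", ~df["action"].isin(ACTIONS))
    flag("rank_enum", ~df["physician_rank"].isin(RANKS))
    flag("gender_enum", ~df["patient_gender"].isin(GENDERS))
    flag("patient_age_range", ~df["patient_age"].between(0, 130))
    flag("length_of_stay_positive", df["length_of_stay"] < 1)
    flag("diagnosis_count_positive", df["diagnosis_count"] < 1)
    return ValidationReport(valid=not violations, violations=violations)
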