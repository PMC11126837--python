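"""Readers and writers for the delimited-text interchange formats and for
fitted-model files.

File formats
------------
sensor CSV : ``timestamp,<channel columns...>`` with ISO-8601 timestamps;
    the channel schema (column -> role) is supplied by the caller.
sample CSV : ``sample_id,class,conc_oue,ci_low,ci_high``; Air rows may leave
    the concentration columns empty.
wind CSV   : ``timestamp,speed_ms,direction_deg`` (provenance convention).
model files: versioned JSON holding every array needed to reproduce
    predictions bit-identically.

Timestamps are ISO-8601 in files and seconds-since-epoch (UTC) in memory, so
sensor and wind streams merge unambiguously.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    OdorSample,
    SchemaError,
    SensorFrame,
    ValidationError,
    WindRecord,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT = "odormon-model"
MODEL_VERSION = 1


def _to_epoch(series: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def _to_iso(epoch: np.ndarray) -> list[str]:
    ts = pd.to_datetime(np.asarray(epoch) * 1e9, utc=True)
    return [t.strftime("%Y-%m-%dT%H:%M:%S%z") for t in ts]


def read_sensor_csv(path: str | Path, schema: Mapping[str, str]) -> SensorFrame:
    """Parse a sensor CSV into a validated :class:`SensorFrame`.

    Rows whose channel values fail to parse as numbers are dropped with a
    logged count; structural problems (missing mandatory channels,
    non-monotone timestamps, out-of-range values) raise instead.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise SchemaError(f"{path}: missing 'timestamp' column")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory channels {missing}")
    chan = df[list(schema)].apply(pd.to_numeric, errors="coerce")
    bad = chan.isna().all(axis=1) | chan.isna().any(axis=1) & ~df[list(schema)].isna().any(axis=1)
    unparseable = chan.isna() & df[list(schema)].notna()
    drop = unparseable.any(axis=1)
    if drop.any():
        logger.warning("%s: dropped %d rows with unparseable values", path, int(drop.sum()))
        df = df.loc[~drop].reset_index(drop=True)
        chan = chan.loc[~drop].reset_index(drop=True)
    try:
        timestamps = _to_epoch(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable timestamps: {exc}") from exc
    return SensorFrame(timestamps, chan, dict(schema))


def write_sensor_csv(frame: SensorFrame, path: str | Path) -> None:
    out = frame.channels.copy()
    out.insert(0, "timestamp", _to_iso(frame.timestamps))
    out.to_csv(path, index=False)


def read_sample_table(path: str | Path) -> list[OdorSample]:
    """Parse a sample metadata CSV into validated :class:`OdorSample` rows."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"sample_id": str}, skip_blank_lines=True
    )
    if df.empty and df.columns.size == 0:
        return []
    required = {"sample_id", "class"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for i, row in df.iterrows():
        def _num(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        try:
            samples.append(
                OdorSample(
                    sample_id=str(row["sample_id"]),
                    class_label=str(row["class"]),
                    concentration=_num("conc_oue"),
                    ci_low=_num("ci_low"),
                    ci_high=_num("ci_high"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return samples


def write_sample_table(samples: list[OdorSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "class": s.class_label,
            "conc_oue": s.concentration,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "class", "conc_oue", "ci_low", "ci_high"]).to_csv(
        path, index=False
    )


def read_wind_csv(path: str | Path) -> list[WindRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"timestamp", "speed_ms", "direction_deg"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    t = _to_epoch(df["timestamp"])
    records = []
    for i in range(len(df)):
        try:
            records.append(
                WindRecord(float(t[i]), float(df["speed_ms"].iloc[i]),
                           float(df["direction_deg"].iloc[i]) % 360.0)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def write_wind_csv(records: list[WindRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": _to_iso(np.array([r.timestamp for r in records])),
            "speed_ms": [r.speed for r in records],
            "direction_deg": [r.direction for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model serialization: versioned JSON, arrays as nested lists.  Each model
# class implements to_dict()/from_dict(); the registry maps type tags.

def _model_registry() -> dict:
    from .classify import KnnClassifier, SwLinearClassifier
    from .quantify import DoubleStepModel, GlobalPlsModel, PlsModel

    return {
        cls.__name__: cls
        for cls in (KnnClassifier, SwLinearClassifier, PlsModel, DoubleStepModel, GlobalPlsModel)
    }


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to versioned JSON text."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "type": type(model).__name__,
        "state": model.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`.

    Raises an explicit error on truncated files or version mismatches; a
    newer file format is never silently reinterpreted.
    """
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file (truncated or corrupt): {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not an {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(
            f"{path}: model file version {payload.get('version')} "
            f"unsupported (expected {MODEL_VERSION})"
        )
    registry = _model_registry()
    tag = payload.get("type")
    if tag not in registry:
        raise ValueError(f"{path}: unknown model type {tag!r}")
    return registry[tag].from_dict(payload["state"])
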