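"""Monitoring analytics: apply trained models to ambient-air streams and
turn the detections into events, frequencies, wind-filtered impact figures
and a fenceline-receptor correlation table.

Wind is handled in the meteorological provenance convention throughout (the
bearing the wind blows FROM, 0 = North, clockwise).  A receptor detection of
a landfill odor is plausible only when the wind comes from the sector around
the source bearing; detections under incompatible wind are treated as false
positives for the impact assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AIR,
    LANDFILL_CLASSES,
    SensorFrame,
    ValidationError,
    WindRecord,
    circular_difference,
    degrees_to_compass,
)
from .features import WindowPolicy, extract_features, stream_baseline

__all__ = [
    "DetectionRecord",
    "OdorEvent",
    "classify_stream",
    "detect_events",
    "detection_frequencies",
    "wind_filter",
    "odor_impact",
    "correlate_events",
    "threshold_analysis",
]

AREA_LIMITS = {"residential_mixed": 10.0, "industrial_agricultural": 15.0}


@dataclass
class DetectionRecord:
    """Model output for one analysis window of a monitoring stream."""

    timestamp: float                 # window start, epoch seconds
    site: str                        # 'fenceline' | 'receptor'
    label: str
    concentration: float | None = None   # ou_eq, fenceline non-Air only
    wind_speed: float | None = None
    wind_direction: float | None = None
    wind_status: str = ""            # '', 'unassessable'

    def __post_init__(self) -> None:
        if self.site not in ("fenceline", "receptor"):
            raise ValidationError(f"unknown site {self.site!r}")


@dataclass
class OdorEvent:
    """A contiguous non-Air detection episode at one site."""

    site: str
    class_label: str
    start: float
    duration_min: float
    peak_concentration: float | None = None
    mean_concentration: float | None = None
    wind_category: str | None = None
    wind_from_deg: float | None = None

    @property
    def end(self) -> float:
        return self.start + 60.0 * self.duration_min


def classify_stream(
    model,
    frame: SensorFrame,
    site: str = "fenceline",
    window_s: float = 600.0,
    policy: WindowPolicy = WindowPolicy(),
    baseline_context_s: float = 7200.0,
    max_skip: int = 2,
) -> list[DetectionRecord]:
    """Process a monitoring stream into one detection record per analysis
    window.

    Windows containing a data gap (interval longer than ``max_skip``
    sampling periods, e.g. the receptor's periodic calibration pauses) yield
    no record.  The per-window baseline is the per-channel median of the
    trailing ``baseline_context_s`` of signal, so episode windows are
    referenced to recent (mostly clean) air rather than to themselves.
    """
    if len(frame) < 2:
        raise ValidationError("stream too short")
    period = frame.period
    t_start, t_end = frame.timestamps[0], frame.timestamps[-1]
    records: list[DetectionRecord] = []
    quantifies = hasattr(model, "regressors")
    t0 = t_start
    while t0 + window_s <= t_end + period:
        win = frame.slice_time(t0, t0 + window_s)
        if len(win) < max(policy.min_rows, int(0.8 * window_s / period)):
            t0 += window_s
            continue  # gap window: missing rows, no record
        if len(win) > 1 and np.max(np.diff(win.timestamps)) > max_skip * period:
            t0 += window_s
            continue  # internal gap
        ctx = frame.slice_time(max(t_start, t0 - baseline_context_s), t0)
        if len(ctx) < policy.min_rows:
            ctx = win  # stream start: only the window itself is available
        base = stream_baseline(ctx)
        fv = extract_features(win, policy, sample_id=f"{site}@{t0:.0f}", baseline=base)
        if quantifies:
            res = model.predict(fv.features)
            records.append(
                DetectionRecord(t0, site, res.label, res.concentration)
            )
        else:
            label, _ = model.predict(fv.features)
            records.append(DetectionRecord(t0, site, label))
        t0 += window_s
    return records


def detect_events(
    records: list[DetectionRecord],
    min_duration_min: float = 10.0,
    max_gap: int = 2,
    window_s: float | None = None,
) -> list[OdorEvent]:
    """Aggregate detection records into odor events.

    An event is a maximal run of windows with the same non-Air class,
    tolerating interruptions of at most ``max_gap`` windows, kept only if
    its total duration reaches ``min_duration_min`` minutes."""
    recs = sorted(records, key=lambda r: r.timestamp)
    if not recs:
        return []
    if window_s is None:
        ts = [r.timestamp for r in recs]
        window_s = float(np.median(np.diff(ts))) if len(ts) > 1 else 600.0
    events: list[OdorEvent] = []
    run: list[DetectionRecord] = []
    gap = 0

    def _close(run: list[DetectionRecord]) -> None:
        if not run:
            return
        duration = (run[-1].timestamp - run[0].timestamp + window_s) / 60.0
        if duration < min_duration_min:
            return
        concs = [r.concentration for r in run if r.concentration is not None]
        events.append(
            OdorEvent(
                site=run[0].site,
                class_label=run[0].label,
                start=run[0].timestamp,
                duration_min=duration,
                peak_concentration=max(concs) if concs else None,
                mean_concentration=float(np.mean(concs)) if concs else None,
            )
        )

    for r in recs:
        if run and r.label == run[0].label:
            run.append(r)
            gap = 0
        elif run and r.label != run[0].label and gap < max_gap:
            gap += 1
        else:
            _close(run)
            run, gap = ([r] if r.label != AIR else []), 0
        if not run and r.label != AIR:
            run = [r]
    _close(run)
    return events


def detection_frequencies(records: list[DetectionRecord]) -> dict[str, float]:
    """Percent of (non-gap) monitoring time per detected class."""
    if not records:
        raise ValidationError("no detection records")
    counts = pd.Series([r.label for r in records]).value_counts()
    return {label: 100.0 * n / len(records) for label, n in counts.items()}


def _nearest_wind(wind: list[WindRecord], t: float, tolerance: float) -> WindRecord | None:
    if not wind:
        return None
    times = np.array([w.timestamp for w in wind])
    i = int(np.argmin(np.abs(times - t)))
    return wind[i] if abs(times[i] - t) <= tolerance else None


def wind_filter(
    receptor_records: list[DetectionRecord],
    wind: list[WindRecord],
    source_bearing: float,
    half_angle: float = 45.0,
) -> tuple[list[DetectionRecord], list[DetectionRecord]]:
    """Partition receptor landfill detections by wind compatibility.

    A landfill-class detection is kept iff the wind provenance at its
    timestamp lies within +/- ``half_angle`` of ``source_bearing``
    (closed sector, circular arithmetic); incompatible ones are returned
    separately as false positives.  Air/unknown records pass through, and a
    record with no wind reading within one sampling period is kept flagged
    'unassessable'."""
    recs = sorted(receptor_records, key=lambda r: r.timestamp)
    if len(recs) > 1:
        tolerance = float(np.median(np.diff([r.timestamp for r in recs])))
    else:
        tolerance = 600.0
    kept: list[DetectionRecord] = []
    false_pos: list[DetectionRecord] = []
    for r in recs:
        if r.label not in LANDFILL_CLASSES:
            kept.append(r)
            continue
        w = _nearest_wind(wind, r.timestamp, tolerance)
        if w is None:
            warnings.warn(f"no wind reading near t={r.timestamp}; record kept unassessed")
            r.wind_status = "unassessable"
            kept.append(r)
            continue
        r.wind_speed, r.wind_direction = w.speed, w.direction
        if circular_difference(w.direction, source_bearing) <= half_angle:
            kept.append(r)
        else:
            false_pos.append(r)
    return kept, false_pos


def odor_impact(records: list[DetectionRecord], area_type: str) -> tuple[float, bool]:
    """Odor impact as percent of monitoring time with landfill-class
    detections, judged against the odor-hour acceptability limit for the
    area type (10% residential/mixed, 15% industrial/agricultural)."""
    if area_type not in AREA_LIMITS:
        raise ValidationError(f"unknown area type {area_type!r}")
    if not records:
        return 0.0, True
    n_odor = sum(r.label in LANDFILL_CLASSES for r in records)
    impact = 100.0 * n_odor / len(records)
    return impact, impact < AREA_LIMITS[area_type]


def _prevailing_wind(wind: list[WindRecord], t0: float, t1: float):
    sel = [w for w in wind if t0 <= w.timestamp < t1]
    if not sel:
        return None, None
    cats = pd.Series([w.category for w in sel]).mode()
    ang = np.deg2rad([w.direction for w in sel])
    mean_dir = float(np.rad2deg(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))) % 360.0)
    return str(cats.iloc[0]), mean_dir


def correlate_events(
    fenceline_events: list[OdorEvent],
    receptor_events: list[OdorEvent],
    wind: list[WindRecord] | None = None,
) -> pd.DataFrame:
    """Pair fenceline and receptor odor events into one correlation table.

    Events are matched by interval overlap; an event with no counterpart at
    the other site is reported against 'Air' there.  Each row carries the
    fenceline peak concentration and the prevailing wind category and
    provenance -> destination description over the event window."""
    wind = wind or []
    used_receptor: set[int] = set()
    rows = []

    def _wind_cols(t0: float, t1: float) -> dict:
        cat, mean_dir = _prevailing_wind(wind, t0, t1)
        if mean_dir is None:
            return {"wind_category": None, "wind_from_deg": None,
                    "wind_from": None, "wind_to": None}
        return {
            "wind_category": cat,
            "wind_from_deg": mean_dir,
            "wind_from": degrees_to_compass(mean_dir),
            "wind_to": degrees_to_compass(mean_dir + 180.0),
        }

    for fe in sorted(fenceline_events, key=lambda e: e.start):
        match = None
        for j, re_ in enumerate(receptor_events):
            if j in used_receptor:
                continue
            if fe.start < re_.end and re_.start < fe.end:
                match, used_receptor = (j, used_receptor | {j})
                break
        rec_cls = receptor_events[match].class_label if match is not None else AIR
        rows.append({
            "start": fe.start,
            "duration_min": fe.duration_min,
            "receptor_class": rec_cls,
            "fenceline_class": fe.class_label,
            "fenceline_conc": fe.peak_concentration,
            **_wind_cols(fe.start, fe.end),
        })
    for j, re_ in enumerate(sorted(receptor_events, key=lambda e: e.start)):
        if j in used_receptor:
            continue
        rows.append({
            "start": re_.start,
            "duration_min": re_.duration_min,
            "receptor_class": re_.class_label,
            "fenceline_class": AIR,
            "fenceline_conc": None,
            **_wind_cols(re_.start, re_.end),
        })
    df = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    df.insert(0, "event_no", df.index + 1)
    return df


def threshold_analysis(
    table: pd.DataFrame,
    threshold: float,
    source_bearing: float = 0.0,
    half_angle: float = 45.0,
) -> dict[str, dict[str, int]]:
    """Confusion counts of fenceline warning-threshold rules against
    receptor outcomes.

    For the *fixed* rule, an alarm fires when the fenceline concentration
    reaches ``threshold``.  The *wind-conditioned* rule additionally
    requires wind provenance within the compatibility sector of the source
    bearing and non-strong wind — the conditions under which fenceline odor
    can physically reach the receptor.  Rows count (alarm & receptor event),
    (alarm & none), (no alarm & event), (no alarm & none) for each rule.
    """
    required = {"fenceline_conc", "receptor_class", "wind_category", "wind_from_deg"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"correlation table missing columns {sorted(missing)}")
    conc = pd.to_numeric(table["fenceline_conc"], errors="coerce").fillna(0.0)
    event = table["receptor_class"].isin(LANDFILL_CLASSES)
    exceed = conc >= threshold
    compat = table["wind_from_deg"].apply(
        lambda d: (not pd.isna(d)) and circular_difference(float(d), source_bearing) <= half_angle
    )
    calm = table["wind_category"] != "strong"
    alarm_wind = exceed & compat & calm

    def _counts(alarm: pd.Series) -> dict[str, int]:
        return {
            "alarm_event": int((alarm & event).sum()),
            "alarm_no_event": int((alarm & ~event).sum()),
            "no_alarm_event": int((~alarm & event).sum()),
            "no_alarm_no_event": int((~alarm & ~event).sum()),
        }

    return {"fixed": _counts(exceed), "wind_conditioned": _counts(alarm_wind)}
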