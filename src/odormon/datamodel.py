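"""Core domain types shared by every stage of the odor-monitoring pipeline.

The package models a two-instrument setup: a multichannel electronic nose at
a plant fenceline (MOS resistances plus electrochemical H2S/NH3 channels) and
a second unit at a distant receptor.  All stages exchange data through the
types defined here: raw time series (:class:`SensorFrame`), labelled samples
with olfactometric reference concentrations (:class:`OdorSample`), extracted
feature vectors, assembled training sets and wind records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AIR",
    "FRESH_WASTE",
    "LANDFILL_GAS",
    "LEACHATE",
    "ODOR_CLASSES",
    "LANDFILL_CLASSES",
    "normalize_class",
    "ValidationError",
    "SchemaError",
    "SensorFrame",
    "OdorSample",
    "FeatureVector",
    "TrainingSet",
    "WindRecord",
    "wind_category",
    "compass_to_degrees",
    "degrees_to_compass",
    "circular_difference",
]

# Canonical class vocabulary.
AIR = "Air"
FRESH_WASTE = "Fresh Waste"
LANDFILL_GAS = "Landfill Gas"
LEACHATE = "Leachate"
ODOR_CLASSES = (AIR, FRESH_WASTE, LANDFILL_GAS, LEACHATE)
LANDFILL_CLASSES = (FRESH_WASTE, LANDFILL_GAS, LEACHATE)

_CLASS_ALIASES = {
    "air": AIR,
    "freshwaste": FRESH_WASTE,
    "fresh waste": FRESH_WASTE,
    "fresh_waste": FRESH_WASTE,
    "landfillgas": LANDFILL_GAS,
    "landfill gas": LANDFILL_GAS,
    "landfill_gas": LANDFILL_GAS,
    "leachate": LEACHATE,
}


def normalize_class(label: str) -> str:
    """Map spelling variants (``"Landfill gas"``, ``"FreshWaste"``) onto the
    canonical class names.  Unknown labels are returned unchanged (monitoring
    streams may legitimately contain ``"Unknown"``)."""
    key = str(label).strip().lower().replace("-", " ")
    return _CLASS_ALIASES.get(key, str(label).strip())


class ValidationError(ValueError):
    """An input violates a typed invariant (row-addressable message)."""


class SchemaError(ValueError):
    """A file or vector does not match the declared channel/feature schema."""


# Channel roles recognised in sensor schemas.
CHANNEL_ROLES = ("mos", "ec", "temp", "rh")


@dataclass
class SensorFrame:
    """Timestamped multichannel sensor readings for one analysis or a stream.

    Parameters
    ----------
    timestamps : ndarray of float
        Seconds since epoch, strictly increasing, nominally uniform.
    channels : DataFrame
        One named column per channel, one row per timestamp.  MOS channels
        hold electrical resistance in ohm, electrochemical channels analyte
        concentration in ppm, plus temperature (degC) and relative
        humidity (%).
    schema : mapping channel name -> role in {"mos", "ec", "temp", "rh"}.
    """

    timestamps: np.ndarray
    channels: pd.DataFrame
    schema: Mapping[str, str]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValidationError("timestamps must be one-dimensional")
        if len(self.timestamps) != len(self.channels):
            raise ValidationError(
                f"{len(self.timestamps)} timestamps vs {len(self.channels)} channel rows"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.argmin(np.diff(self.timestamps) > 0))
            raise ValidationError(f"timestamps not strictly increasing at row {bad + 1}")
        unknown = set(self.channels.columns) - set(self.schema)
        if unknown:
            raise SchemaError(f"channels missing from schema: {sorted(unknown)}")
        for name, role in self.schema.items():
            if role not in CHANNEL_ROLES:
                raise SchemaError(f"unknown role {role!r} for channel {name!r}")
            if name not in self.channels.columns:
                raise SchemaError(f"schema channel {name!r} absent from data")
        self._validate_values()

    def _validate_values(self) -> None:
        for name, role in self.schema.items():
            col = self.channels[name].to_numpy(dtype=float)
            finite = np.isfinite(col)
            if role == "mos" and np.any(col[finite] <= 0):
                row = int(np.flatnonzero(finite & (col <= 0))[0])
                raise ValidationError(
                    f"MOS channel {name!r} row {row}: resistance {col[row]} must be > 0"
                )
            if role == "rh":
                bad = finite & ((col < 0) | (col > 100))
                if np.any(bad):
                    row = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"RH channel {name!r} row {row}: {col[row]} outside [0, 100]"
                    )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.columns)

    @property
    def period(self) -> float:
        """Nominal sampling period (median inter-sample interval), seconds."""
        if len(self.timestamps) < 2:
            raise ValidationError("period undefined for frames with < 2 rows")
        return float(np.median(np.diff(self.timestamps)))

    def gap_mask(self, max_skip: int = 2) -> np.ndarray:
        """Boolean per-row mask; True where the row follows a data gap longer
        than ``max_skip`` sampling periods.

        The receptor instrument pauses periodically for automatic calibration,
        so gaps are expected; they are marked rather than interpolated to
        avoid fabricating detections.
        """
        mask = np.zeros(len(self.timestamps), dtype=bool)
        if len(self.timestamps) < 2:
            return mask
        dt = np.diff(self.timestamps)
        mask[1:] = dt > max_skip * self.period
        return mask

    def fill_missing(self, max_skip: int = 2) -> "SensorFrame":
        """Forward-fill NaN channel values up to ``max_skip`` consecutive rows;
        longer runs stay NaN (treated as gaps downstream)."""
        filled = self.channels.ffill(limit=max_skip)
        return SensorFrame(self.timestamps.copy(), filled, dict(self.schema))

    def slice_time(self, t0: float, t1: float) -> "SensorFrame":
        """Rows with t0 <= timestamp < t1."""
        sel = (self.timestamps >= t0) & (self.timestamps < t1)
        return SensorFrame(
            self.timestamps[sel], self.channels.loc[sel].reset_index(drop=True), dict(self.schema)
        )


@dataclass(frozen=True)
class OdorSample:
    """A labelled analysis: odor class plus, for odorous samples, the
    reference odor concentration measured by dynamic olfactometry
    (European odor units per cubic metre) with its 95% confidence interval."""

    sample_id: str
    class_label: str
    concentration: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_label", normalize_class(self.class_label))
        if self.class_label not in ODOR_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown class {self.class_label!r}"
            )
        if self.class_label != AIR:
            if self.concentration is None or not self.concentration > 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: non-Air sample needs concentration > 0"
                )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError(
                f"sample {self.sample_id!r}: confidence interval needs both bounds"
            )
        if self.ci_low is not None and self.concentration is not None:
            if not (self.ci_low <= self.concentration <= self.ci_high):
                raise ValidationError(
                    f"sample {self.sample_id!r}: CI [{self.ci_low}, {self.ci_high}] "
                    f"does not bracket concentration {self.concentration}"
                )

    @property
    def is_air(self) -> bool:
        return self.class_label == AIR


@dataclass
class FeatureVector:
    """Named real-valued features extracted from one analysis window."""

    sample_id: str
    features: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.isna().any():
            bad = list(self.features.index[self.features.isna()])
            raise ValidationError(f"feature vector {self.sample_id!r}: NaN in {bad}")


@dataclass
class TrainingSet:
    """Feature matrix plus labels, log10 concentration targets and the
    autoscaling parameters shared by all downstream models.

    ``y_logc`` is defined only for odorous rows (NaN on Air rows): clean
    ambient air has no odor concentration to regress on.
    """

    X: pd.DataFrame
    y_class: pd.Series
    y_logc: pd.Series
    scaler_mean: pd.Series
    scaler_sd: pd.Series

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.y_class) == len(self.y_logc) == n):
            raise ValidationError("X, y_class and y_logc must align row-wise")
        if not (self.X.index.equals(self.y_class.index) and self.X.index.equals(self.y_logc.index)):
            raise ValidationError("X, y_class and y_logc must share an index")
        if (self.scaler_sd <= 0).any():
            bad = list(self.scaler_sd.index[self.scaler_sd <= 0])
            raise ValidationError(f"autoscaling SD must be > 0; offending features: {bad}")
        air = self.y_class == AIR
        if self.y_logc[air].notna().any():
            raise ValidationError("Air rows must not carry a regression target")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def scale(self, X: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
        """Autoscale (center, unit variance) using the stored parameters."""
        return (X - self.scaler_mean) / self.scaler_sd

    def unscale(self, Xs: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
        return Xs * self.scaler_sd + self.scaler_mean

    @property
    def X_scaled(self) -> pd.DataFrame:
        return self.scale(self.X)

    def odorous(self) -> "TrainingSet":
        """Subset of non-Air rows (the quantification training data)."""
        keep = self.y_class != AIR
        return TrainingSet(
            self.X.loc[keep], self.y_class.loc[keep], self.y_logc.loc[keep],
            self.scaler_mean, self.scaler_sd,
        )


def wind_category(speed_ms: float) -> str:
    """Categorise wind speed: 'absent' (<=1 m/s), 'weak' (1-2 m/s),
    'strong' (2-5 m/s); above 5 m/s reported as 'strong' with a warning."""
    if speed_ms < 0:
        raise ValidationError(f"negative wind speed {speed_ms}")
    if speed_ms <= 1.0:
        return "absent"
    if speed_ms <= 2.0:
        return "weak"
    if speed_ms > 5.0:
        warnings.warn(f"wind speed {speed_ms} m/s above the 5 m/s category scale")
    return "strong"


@dataclass(frozen=True)
class WindRecord:
    """One anemometer reading.  ``direction`` follows the meteorological
    provenance convention: the bearing the wind blows FROM, degrees clockwise
    from North."""

    timestamp: float
    speed: float
    direction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.direction < 360.0):
            raise ValidationError(f"wind direction {self.direction} outside [0, 360)")
        wind_category(self.speed)  # validates speed

    @property
    def category(self) -> str:
        return wind_category(self.speed)


# 16-point compass rose, provenance bearings.
_COMPASS = [
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
]


def compass_to_degrees(point: str) -> float:
    """Bearing in degrees of a 16-point compass label (N = 0, clockwise)."""
    p = point.strip().upper()
    if p not in _COMPASS:
        raise ValueError(f"unknown compass point {point!r}")
    return _COMPASS.index(p) * 22.5


def degrees_to_compass(deg: float) -> str:
    """Nearest 16-point compass label for a bearing in degrees."""
    idx = int(np.round((deg % 360.0) / 22.5)) % 16
    return _COMPASS[idx]


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Smallest absolute angular difference between two bearings, in [0, 180]."""
    d = abs((a_deg - b_deg) % 360.0)
    return min(d, 360.0 - d)
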