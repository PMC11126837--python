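"""Feature extraction from raw sensor time series and training-set assembly.

Each channel contributes two features: the steady-state level over the tail
of the analysis window and the baseline-relative response (level minus
pre-exposure baseline).  MOS resistances are taken to log10 scale first —
MOS response follows a power law in analyte concentration, so log
resistance is the scale on which the downstream linear models are sensible;
electrochemical, temperature and humidity channels stay in native units.

Features with heterogeneous units (ohm-decades, ppm, %, degC) are made
commensurable by autoscaling (per-feature centering and unit variance),
applied identically before PCA, k-NN and PLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AIR,
    FeatureVector,
    OdorSample,
    SensorFrame,
    TrainingSet,
    ValidationError,
)

__all__ = ["WindowPolicy", "extract_features", "build_training_set"]


@dataclass(frozen=True)
class WindowPolicy:
    """How an analysis window is split into baseline and steady-state parts.

    baseline_fraction : leading fraction of the window averaged as the
        pre-exposure baseline (ignored when an explicit baseline is given).
    steady_fraction : trailing fraction averaged as the steady-state level.
    min_rows : minimum window length in samples.
    """

    baseline_fraction: float = 0.2
    steady_fraction: float = 0.5
    min_rows: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.baseline_fraction < 1 and 0 < self.steady_fraction < 1):
            raise ValidationError("window fractions must lie in (0, 1)")
        if self.baseline_fraction + self.steady_fraction > 1:
            raise ValidationError("baseline and steady-state segments overlap")


def _feature_scale(values: np.ndarray, role: str) -> np.ndarray:
    return np.log10(values) if role == "mos" else values


def extract_features(
    frame: SensorFrame,
    policy: WindowPolicy = WindowPolicy(),
    sample_id: str = "",
    baseline: pd.Series | None = None,
) -> FeatureVector:
    """Extract per-channel (level, delta) features from one analysis window.

    ``level`` is the mean over the trailing ``steady_fraction`` of the
    window; ``delta`` is level minus the pre-exposure baseline (mean of the
    leading ``baseline_fraction``, or the explicit ``baseline`` override used
    for monitoring streams where the instrument has no clean pre-exposure
    segment).  Zero-variance channels are flagged in the metadata, not
    dropped — a flat-lined sensor is an instrument fault worth surfacing.
    """
    n = len(frame)
    if n < policy.min_rows:
        raise ValidationError(f"window of {n} rows shorter than minimum {policy.min_rows}")
    n_base = max(1, int(np.floor(n * policy.baseline_fraction)))
    n_steady = max(1, int(np.floor(n * policy.steady_fraction)))
    feats: dict[str, float] = {}
    flat: list[str] = []
    for ch in frame.channel_names:
        role = frame.schema[ch]
        x = _feature_scale(frame.channels[ch].to_numpy(dtype=float), role)
        level = float(np.mean(x[-n_steady:]))
        if baseline is not None:
            if ch not in baseline.index:
                raise ValidationError(f"explicit baseline missing channel {ch!r}")
            base = float(baseline[ch])
        else:
            base = float(np.mean(x[:n_base]))
        feats[f"{ch}:level"] = level
        feats[f"{ch}:delta"] = level - base
        if np.ptp(x) == 0.0:
            flat.append(ch)
    meta = {
        "t_start": float(frame.timestamps[0]),
        "t_end": float(frame.timestamps[-1]),
        "flat_channels": flat,
    }
    return FeatureVector(sample_id=sample_id, features=pd.Series(feats), metadata=meta)


def stream_baseline(frame: SensorFrame) -> pd.Series:
    """Per-channel baseline for monitoring streams: the median of the
    feature-scale signal over a trailing context window.

    The median is unbiased on clean air (an asymmetric low/high quantile
    would fake a small response pattern on every window) and robust as long
    as odor episodes occupy less than half of the context."""
    vals = {}
    for ch in frame.channel_names:
        x = _feature_scale(frame.channels[ch].to_numpy(dtype=float), frame.schema[ch])
        vals[ch] = float(np.median(x))
    return pd.Series(vals)


def build_training_set(
    samples: list[OdorSample], feature_vectors: list[FeatureVector]
) -> TrainingSet:
    """Assemble the model-ready frame: feature matrix, class labels,
    log10-concentration targets for odorous rows, autoscaling parameters.

    Zero-variance features are dropped with a warning (they carry no
    information and break autoscaling); duplicated sample ids are an error.
    """
    if len(samples) != len(feature_vectors):
        raise ValidationError(
            f"{len(samples)} samples vs {len(feature_vectors)} feature vectors"
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicated sample ids: {dup}")
    by_id = {fv.sample_id: fv for fv in feature_vectors}
    if set(by_id) != set(ids):
        # fall back to positional pairing when extractor wasn't given ids
        rows = [fv.features for fv in feature_vectors]
    else:
        rows = [by_id[i].features for i in ids]
    X = pd.DataFrame(rows)
    X.index = pd.Index(ids, name="sample_id")
    if X.isna().any().any():
        raise ValidationError("feature schema differs across samples")
    sd = X.std(ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(index=dead)
    y_class = pd.Series([s.class_label for s in samples], index=X.index, name="class")
    y_logc = pd.Series(
        [np.log10(s.concentration) if not s.is_air else np.nan for s in samples],
        index=X.index, name="log10_conc",
    )
    return TrainingSet(X=X, y_class=y_class, y_logc=y_logc,
                       scaler_mean=X.mean(), scaler_sd=sd)
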