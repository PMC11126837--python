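"""Bundled reference datasets from a landfill fenceline/receptor monitoring
campaign.

Two small tables ship with the package:

``field_validation`` — 12 odorous field-test samples analysed in parallel by
dynamic olfactometry (concentration with 95% CI, odor units/m^3) and by the
fenceline instrument (predicted class plus the double-step and global model
concentration estimates, ou_eq).  This is the worked example for the
agreement analysis.

``monitoring_events`` — the odor-event log of a month of two-site
monitoring: per event, duration, class detected at the receptor and at the
fenceline, fenceline concentration estimate and the prevailing wind
(speed category and provenance -> destination compass points).  This is the
worked example for the warning-threshold analytics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datamodel import OdorSample, compass_to_degrees, normalize_class

__all__ = [
    "load_validation_table",
    "validation_samples",
    "validation_predictions",
    "load_event_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("odormon.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_validation_table() -> pd.DataFrame:
    """The field-validation table: olfactometry vs instrument estimates."""
    df = _read("field_validation.csv")
    df["class"] = df["class"].map(normalize_class)
    df["predicted_class"] = df["predicted_class"].map(normalize_class)
    return df


def validation_samples() -> list[OdorSample]:
    """The validation table as :class:`OdorSample` objects."""
    return [
        OdorSample(str(r.sample_id), r["class"], float(r.conc_oue),
                   float(r.ci_low), float(r.ci_high))
        for _, r in load_validation_table().iterrows()
    ]


def validation_predictions(model: str = "a") -> dict[str, float]:
    """Instrument concentration estimates keyed by sample id, for the
    double-step model (``'a'``) or the global model (``'b'``)."""
    col = {"a": "pred_model_a", "b": "pred_model_b"}[model.lower()]
    df = load_validation_table()
    return {str(sid): float(v) for sid, v in zip(df["sample_id"], df[col])}


def load_event_table() -> pd.DataFrame:
    """The monitoring odor-event log, with wind provenance also resolved to
    degrees (``wind_from_deg``) for sector arithmetic."""
    df = _read("monitoring_events.csv")
    for col in ("receptor_class", "fenceline_class"):
        df[col] = df[col].map(normalize_class)
    df["wind_from_deg"] = df["wind_from"].map(compass_to_degrees)
    return df
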