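"""Synthetic electronic-nose data: single analyses, training campaigns and
monitoring scenarios with wind.

The generator emulates a landfill monitoring study in which the real sensor
data are confidential: four odor classes (clean Air plus the three landfill
sources Fresh Waste, Landfill Gas and Leachate), each with a distinct sensor
fingerprint, a log-linear concentration-response law, humidity coupling,
additive Gaussian channel noise, and a two-site monitoring scenario where a
receptor ~2 km downwind perceives fenceline emissions only under compatible
wind.

Response law
------------
Each channel j has a baseline level ``b0_j`` on its *feature* scale (log10
resistance for MOS channels, ppm for electrochemical channels).  Exposure to
class c at concentration C (odor units per m^3) shifts the steady-state
level by ``b_cj * log10(C / C_ref)`` provided C is at or above the channel's
detection floor; below the floor the channel stays at baseline.  Relative
humidity couples linearly with per-channel coefficient ``gamma_j``.  MOS
channels are materialised as resistances ``10**level`` so raw frames carry
ohm; transients rise exponentially with time constant ``tau_s``.

Channels are simulated directly at their steady-state feature level (plus
the optional exponential rise) rather than as full sensor kinetics: the
downstream pipeline consumes window features, not transient shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AIR,
    FRESH_WASTE,
    LANDFILL_GAS,
    LANDFILL_CLASSES,
    LEACHATE,
    OdorSample,
    SensorFrame,
    ValidationError,
    WindRecord,
    normalize_class,
)

__all__ = [
    "SimParams",
    "EmissionEpisode",
    "ScenarioParams",
    "GroundTruth",
    "fenceline_params",
    "receptor_params",
    "default_scenario",
    "simulate_sample_response",
    "simulate_training_campaign",
    "simulate_monitoring_scenario",
]


@dataclass
class SimParams:
    """Parameters of the sensor-array simulator for one instrument.

    ``fingerprints`` maps each odor class to per-channel response slopes
    (feature-scale units per decade of concentration); distinct classes must
    have distinct directions, which is what makes classify-then-regress
    meaningful on this generator.
    """

    seed: int
    schema: Mapping[str, str]
    baseline: Mapping[str, float]
    noise_sd: Mapping[str, float]
    humidity_gamma: Mapping[str, float]
    fingerprints: Mapping[str, Mapping[str, float]]
    detection_floor: Mapping[str, float]
    response_ref: float = 10.0   # concentration with zero log response term
    rh_ref: float = 50.0
    rh_sd: float = 5.0
    tau_s: float = 30.0
    period_s: float = 10.0
    # training-campaign layout: per-class source-sample counts and
    # concentration ranges (odor units / m^3)
    class_sources: Mapping[str, int] = field(
        default_factory=lambda: {FRESH_WASTE: 8, LANDFILL_GAS: 10, LEACHATE: 10}
    )
    class_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            FRESH_WASTE: (50.0, 310.0),
            LANDFILL_GAS: (60.0, 700.0),
            LEACHATE: (50.0, 620.0),
        }
    )
    n_air: int = 24
    dilutions_per_source: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimParams.seed is mandatory")
        for ch, sd in self.noise_sd.items():
            if not sd > 0:
                raise ValidationError(f"noise SD for channel {ch!r} must be > 0")
        classes = [c for c in self.fingerprints if c != AIR]
        gas = self.gas_channels
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                va = np.array([self.fingerprints[a].get(ch, 0.0) for ch in gas])
                vb = np.array([self.fingerprints[b].get(ch, 0.0) for ch in gas])
                cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
                if cos > 0.9999:
                    raise ValidationError(f"fingerprints of {a!r} and {b!r} are not distinct")

    @property
    def gas_channels(self) -> list[str]:
        return [ch for ch, role in self.schema.items() if role in ("mos", "ec")]

    @property
    def channel_names(self) -> list[str]:
        return list(self.schema)


def fenceline_params(seed: int) -> SimParams:
    """Defaults emulating the fenceline unit: 4 MOS + H2S/NH3 electrochemical
    channels, 10 s sampling, detection floors at 50 odor units/m^3."""
    schema = {
        "mos_1": "mos", "mos_2": "mos", "mos_3": "mos", "mos_4": "mos",
        "ec_h2s": "ec", "ec_nh3": "ec", "temp_c": "temp", "rh_pct": "rh",
    }
    baseline = {
        "mos_1": 5.0, "mos_2": 5.2, "mos_3": 4.8, "mos_4": 5.1,
        "ec_h2s": 0.02, "ec_nh3": 0.05, "temp_c": 22.0, "rh_pct": 50.0,
    }
    noise = {
        "mos_1": 0.02, "mos_2": 0.02, "mos_3": 0.02, "mos_4": 0.02,
        "ec_h2s": 0.01, "ec_nh3": 0.02, "temp_c": 0.2, "rh_pct": 1.0,
    }
    gamma = {
        "mos_1": -0.003, "mos_2": -0.002, "mos_3": -0.004, "mos_4": -0.002,
        "ec_h2s": 0.0, "ec_nh3": 0.001, "temp_c": 0.0, "rh_pct": 0.0,
    }
    # MOS resistance drops on exposure (negative slope in log10 ohm per
    # decade); electrochemical channels respond in ppm per decade.
    fingerprints = {
        FRESH_WASTE: {"mos_1": -0.45, "mos_2": -0.22, "mos_3": -0.08, "mos_4": -0.30,
                      "ec_h2s": 0.05, "ec_nh3": 0.60},
        LANDFILL_GAS: {"mos_1": -0.18, "mos_2": -0.50, "mos_3": -0.34, "mos_4": -0.10,
                       "ec_h2s": 0.80, "ec_nh3": 0.05},
        LEACHATE: {"mos_1": -0.30, "mos_2": -0.10, "mos_3": -0.50, "mos_4": -0.38,
                   "ec_h2s": 0.30, "ec_nh3": 0.30},
    }
    floor = {ch: 50.0 for ch in ("mos_1", "mos_2", "mos_3", "mos_4", "ec_h2s", "ec_nh3")}
    return SimParams(seed=seed, schema=schema, baseline=baseline, noise_sd=noise,
                     humidity_gamma=gamma, fingerprints=fingerprints, detection_floor=floor)


def receptor_params(seed: int) -> SimParams:
    """Defaults emulating the receptor unit: 6 MOS channels, 60 s sampling,
    higher sensitivity (floors at 20 odor units/m^3), trained on the diluted
    concentration ranges expected 2 km from the source."""
    schema = {f"mos_{i}": "mos" for i in range(1, 7)} | {"temp_c": "temp", "rh_pct": "rh"}
    baseline = {"mos_1": 5.1, "mos_2": 4.9, "mos_3": 5.3, "mos_4": 5.0,
                "mos_5": 4.7, "mos_6": 5.2, "temp_c": 21.0, "rh_pct": 55.0}
    noise = {ch: 0.015 for ch in schema if ch.startswith("mos")} | {"temp_c": 0.2, "rh_pct": 1.0}
    gamma = {ch: -0.003 for ch in schema if ch.startswith("mos")} | {"temp_c": 0.0, "rh_pct": 0.0}
    fingerprints = {
        FRESH_WASTE: {"mos_1": -0.50, "mos_2": -0.20, "mos_3": -0.10,
                      "mos_4": -0.35, "mos_5": -0.15, "mos_6": -0.40},
        LANDFILL_GAS: {"mos_1": -0.15, "mos_2": -0.55, "mos_3": -0.40,
                       "mos_4": -0.10, "mos_5": -0.45, "mos_6": -0.12},
        LEACHATE: {"mos_1": -0.35, "mos_2": -0.12, "mos_3": -0.50,
                   "mos_4": -0.40, "mos_5": -0.10, "mos_6": -0.30},
    }
    floor = {ch: 20.0 for ch in schema if ch.startswith("mos")}
    return SimParams(
        seed=seed, schema=schema, baseline=baseline, noise_sd=noise,
        humidity_gamma=gamma, fingerprints=fingerprints, detection_floor=floor,
        period_s=60.0,
        class_ranges={FRESH_WASTE: (30.0, 260.0), LANDFILL_GAS: (20.0, 300.0),
                      LEACHATE: (30.0, 230.0)},
    )


def _child_seed(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salt)]))


def _steady_response(params: SimParams, class_label: str, concentration: float | None,
                     channel: str) -> float:
    """Steady-state response term of one channel, feature scale."""
    if class_label == AIR:
        return 0.0
    slope = params.fingerprints.get(class_label, {}).get(channel, 0.0)
    floor = params.detection_floor.get(channel, 0.0)
    if concentration < floor:
        return 0.0
    return slope * np.log10(concentration / params.response_ref)


def simulate_sample_response(
    class_label: str,
    concentration: float | None,
    params: SimParams,
    seed: int,
    duration_s: float = 600.0,
    baseline_s: float = 120.0,
    t0: float = 0.0,
    rh_offset: float = 0.0,
) -> SensorFrame:
    """Simulate one analysis: a pre-exposure baseline segment followed by
    exposure with an exponential rise to the steady-state level.

    Deterministic for a fixed seed.  Air samples are baseline plus noise.
    """
    class_label = normalize_class(class_label)
    if class_label != AIR and class_label not in params.fingerprints:
        raise ValidationError(f"unknown odor class {class_label!r}")
    if class_label != AIR and not (concentration and concentration > 0):
        raise ValidationError("non-Air samples need a positive concentration")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, params.period_s)
    rise = np.where(t >= baseline_s, 1.0 - np.exp(-(t - baseline_s) / params.tau_s), 0.0)
    rh = params.rh_ref + rh_offset + rng.normal(0.0, params.noise_sd.get("rh_pct", 1.0), len(t))
    rh = np.clip(rh, 0.0, 100.0)
    data = {}
    for ch, role in params.schema.items():
        if role == "rh":
            data[ch] = rh
            continue
        level = (
            params.baseline[ch]
            + params.humidity_gamma.get(ch, 0.0) * (rh - params.rh_ref)
            + _steady_response(params, class_label, concentration, ch) * rise
            + rng.normal(0.0, params.noise_sd[ch], len(t))
        )
        if role == "mos":
            data[ch] = 10.0 ** level
        elif role == "ec":
            data[ch] = np.clip(level, 0.0, None)
        else:
            data[ch] = level
    return SensorFrame(t0 + t, pd.DataFrame(data, columns=params.channel_names), dict(params.schema))


def simulate_training_campaign(
    params: SimParams, seed: int, duration_s: float = 600.0
) -> tuple[list[OdorSample], list[SensorFrame]]:
    """Generate a full training campaign: odorless ambient-air analyses plus
    per-class dilution series.

    For every source sample, ``dilutions_per_source`` concentrations are
    log-spaced (with mild jitter) across that class's configured range,
    mirroring a protocol where emission samples are measured by dynamic
    olfactometry and then presented diluted to the instrument.  Olfactometric
    95% CIs are attached at roughly a factor 2 around the assigned value,
    the uncertainty characteristic of the panel method.
    """
    samples: list[OdorSample] = []
    frames: list[SensorFrame] = []
    for i in range(params.n_air):
        sid = f"air-{i + 1:02d}"
        samples.append(OdorSample(sid, AIR))
        frames.append(
            simulate_sample_response(AIR, None, params, seed=_spawn_int(seed, 0, i),
                                     duration_s=duration_s,
                                     rh_offset=float(_child_seed(seed, 9, i).normal(0, params.rh_sd)))
        )
    for ci, cls in enumerate(LANDFILL_CLASSES):
        lo, hi = params.class_ranges[cls]
        for src in range(params.class_sources[cls]):
            rng = _child_seed(seed, 1 + ci, src)
            grid = np.geomspace(lo, hi, params.dilutions_per_source)
            jitter = np.exp(rng.normal(0.0, 0.08, len(grid)))
            concs = np.clip(grid * jitter, lo, hi)
            for d, conc in enumerate(concs):
                conc = float(np.round(conc))
                sid = f"{cls.replace(' ', '').lower()}-s{src + 1:02d}-d{d + 1}"
                samples.append(
                    OdorSample(sid, cls, conc, np.floor(conc / 2.3), np.ceil(conc * 2.0))
                )
                frames.append(
                    simulate_sample_response(
                        cls, conc, params, seed=_spawn_int(seed, 10 + ci, src * 100 + d),
                        duration_s=duration_s,
                        rh_offset=float(rng.normal(0, params.rh_sd)),
                    )
                )
    return samples, frames


def _spawn_int(seed: int, *salt: int) -> int:
    """Deterministic 31-bit child seed."""
    return int(np.random.SeedSequence([int(seed), *map(int, salt)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Monitoring scenario


@dataclass(frozen=True)
class EmissionEpisode:
    """One scheduled emission at the fenceline with its wind context."""

    class_label: str
    concentration: float
    start_s: float
    duration_s: float
    wind_from_deg: float
    wind_speed_ms: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class ScenarioParams:
    """Two-site monitoring scenario: a fenceline instrument at the source
    boundary and a receptor instrument downwind.

    ``source_bearing_deg`` is the bearing of the source as seen from the
    receptor (the provenance a wind must have to carry odor there);
    transport attenuates fenceline concentration by ``dilution_factor``.
    Receptor transport is suppressed under strong wind (> 2 m/s), which
    improves atmospheric dilution.
    """

    fenceline: SimParams
    receptor: SimParams
    episodes: Sequence[EmissionEpisode]
    duration_s: float = 20 * 3600.0
    source_bearing_deg: float = 0.0
    sector_half_angle_deg: float = 45.0
    dilution_factor: float = 10.0
    wind_period_s: float = 60.0
    background_wind_from_deg: float = 0.0
    background_wind_speed_ms: float = 1.5
    wind_dir_ar: float = 0.8
    wind_dir_sd: float = 6.0
    wind_speed_sd: float = 0.15

    def __post_init__(self) -> None:
        eps = sorted(self.episodes, key=lambda e: e.start_s)
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s and a.class_label != b.class_label:
                raise ValidationError(
                    "overlapping episodes of different classes are out of modelled scope"
                )
        self.episodes = eps


@dataclass
class GroundTruth:
    """Scored truth for a simulated scenario: the scheduled fenceline
    episodes and, per episode, whether transport rules deliver it to the
    receptor."""

    episodes: list[EmissionEpisode]
    receptor_detected: list[bool]

    def receptor_intervals(self) -> list[tuple[float, float]]:
        return [(e.start_s, e.end_s)
                for e, hit in zip(self.episodes, self.receptor_detected) if hit]


def default_scenario(seed: int) -> ScenarioParams:
    """A 20 h scenario exercising the transport rules: compatible-wind events
    that reach the receptor, off-sector events, sub-floor events and a
    strong-wind event that stays local."""
    h = 3600.0
    episodes = [
        EmissionEpisode(LANDFILL_GAS, 700.0, 2 * h, 60 * 60, 0.0, 1.5),
        EmissionEpisode(LANDFILL_GAS, 400.0, 5 * h, 20 * 60, 135.0, 1.5),
        EmissionEpisode(FRESH_WASTE, 150.0, 8 * h, 30 * 60, 0.0, 1.5),
        EmissionEpisode(LANDFILL_GAS, 340.0, 11 * h, 40 * 60, 45.0, 3.0),
        EmissionEpisode(FRESH_WASTE, 260.0, 14 * h, 30 * 60, 350.0, 1.5),
        EmissionEpisode(LANDFILL_GAS, 90.0, 17 * h, 20 * 60, 0.0, 1.5),
    ]
    return ScenarioParams(
        fenceline=fenceline_params(seed),
        receptor=receptor_params(seed + 1),
        episodes=episodes,
    )


def _episode_reaches_receptor(sc: ScenarioParams, ep: EmissionEpisode) -> bool:
    from .datamodel import circular_difference, wind_category

    compatible = (
        circular_difference(ep.wind_from_deg, sc.source_bearing_deg)
        <= sc.sector_half_angle_deg
    )
    if not compatible or wind_category(ep.wind_speed_ms) == "strong":
        return False
    diluted = ep.concentration / sc.dilution_factor
    floors = [sc.receptor.detection_floor.get(ch, np.inf)
              for ch in sc.receptor.gas_channels]
    return diluted >= min(floors)


def _episode_response_profile(t: np.ndarray, ep_start: float, ep_end: float,
                              tau: float) -> np.ndarray:
    """Exponential rise during the episode and decay afterwards, in [0, 1]."""
    out = np.zeros_like(t)
    during = (t >= ep_start) & (t < ep_end)
    out[during] = 1.0 - np.exp(-(t[during] - ep_start) / tau)
    after = t >= ep_end
    peak = 1.0 - np.exp(-(ep_end - ep_start) / tau)
    out[after] = np.maximum(out[after], peak * np.exp(-(t[after] - ep_end) / tau))
    return out


def _stream_frame(params: SimParams, t: np.ndarray,
                  contributions: list[tuple[EmissionEpisode, float, np.ndarray]],
                  rng: np.random.Generator) -> SensorFrame:
    """Assemble a monitoring stream from baseline + episode contributions.

    ``contributions`` carries (episode, effective concentration at this site,
    rise/decay profile over t)."""
    rh = params.rh_ref + rng.normal(0.0, params.noise_sd.get("rh_pct", 1.0), len(t))
    rh = np.clip(rh, 0.0, 100.0)
    data = {}
    for ch, role in params.schema.items():
        if role == "rh":
            data[ch] = rh
            continue
        level = (
            params.baseline[ch]
            + params.humidity_gamma.get(ch, 0.0) * (rh - params.rh_ref)
            + rng.normal(0.0, params.noise_sd[ch], len(t))
        )
        for ep, conc, profile in contributions:
            level = level + _steady_response(params, ep.class_label, conc, ch) * profile
        if role == "mos":
            data[ch] = 10.0 ** level
        elif role == "ec":
            data[ch] = np.clip(level, 0.0, None)
        else:
            data[ch] = level
    return SensorFrame(t, pd.DataFrame(data, columns=params.channel_names), dict(params.schema))


def simulate_monitoring_scenario(
    sc: ScenarioParams, seed: int
) -> tuple[SensorFrame, SensorFrame, list[WindRecord], GroundTruth]:
    """Simulate fenceline and receptor streams plus wind for one scenario.

    The receptor sees an episode only when (a) the wind provenance lies
    within the configured sector around the source bearing, (b) the wind is
    not strong, and (c) the transported concentration clears the receptor's
    detection floor; the returned :class:`GroundTruth` records both streams'
    episodes for scoring."""
    t_f = np.arange(0.0, sc.duration_s, sc.fenceline.period_s)
    t_r = np.arange(0.0, sc.duration_s, sc.receptor.period_s)
    fence_contrib = [
        (ep, ep.concentration,
         _episode_response_profile(t_f, ep.start_s, ep.end_s, sc.fenceline.tau_s))
        for ep in sc.episodes
    ]
    detected = [_episode_reaches_receptor(sc, ep) for ep in sc.episodes]
    rec_contrib = [
        (ep, ep.concentration / sc.dilution_factor,
         _episode_response_profile(t_r, ep.start_s, ep.end_s, sc.receptor.tau_s))
        for ep, hit in zip(sc.episodes, detected) if hit
    ]
    fence_frame = _stream_frame(sc.fenceline, t_f, fence_contrib, _child_seed(seed, 101))
    rec_frame = _stream_frame(sc.receptor, t_r, rec_contrib, _child_seed(seed, 102))

    # Wind: AR(1) wander of the provenance direction around a target that
    # follows the episode schedule, categorical speed around the target.
    rng = _child_seed(seed, 103)
    t_w = np.arange(0.0, sc.duration_s, sc.wind_period_s)
    records: list[WindRecord] = []
    dev = 0.0
    for tw in t_w:
        target_dir, target_speed = sc.background_wind_from_deg, sc.background_wind_speed_ms
        for ep in sc.episodes:
            if ep.start_s - 600 <= tw < ep.end_s + 600:
                target_dir, target_speed = ep.wind_from_deg, ep.wind_speed_ms
                break
        dev = sc.wind_dir_ar * dev + rng.normal(0.0, sc.wind_dir_sd)
        speed = max(0.05, target_speed + rng.normal(0.0, sc.wind_speed_sd))
        records.append(WindRecord(float(tw), float(speed), float((target_dir + dev) % 360.0)))
    return fence_frame, rec_frame, records, GroundTruth(list(sc.episodes), detected)
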