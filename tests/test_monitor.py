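import numpy as np
import pytest

from odormon import datasets, monitor, simulate
from odormon.datamodel import (
    AIR,
    FRESH_WASTE,
    LANDFILL_CLASSES,
    LANDFILL_GAS,
    WindRecord,
)
from odormon.monitor import (
    DetectionRecord,
    classify_stream,
    correlate_events,
    detect_events,
    detection_frequencies,
    odor_impact,
    threshold_analysis,
    wind_filter,
)


def _records(labels, cadence_s=60.0, site="receptor", concs=None):
    return [
        DetectionRecord(i * cadence_s, site, lab,
                        None if concs is None else concs[i])
        for i, lab in enumerate(labels)
    ]


class TestDetectEvents:
    def test_short_run_below_min_duration_is_no_event(self):
        recs = _records([LANDFILL_GAS] * 9, cadence_s=10.0)
        assert detect_events(recs, min_duration_min=10) == []

    def test_hour_of_windows_is_one_event(self):
        recs = _records([LANDFILL_GAS] * 60, cadence_s=60.0)
        events = detect_events(recs, min_duration_min=10)
        assert len(events) == 1
        assert events[0].duration_min == pytest.approx(60.0)
        assert events[0].class_label == LANDFILL_GAS

    def test_single_air_interruption_merged(self):
        labels = [LANDFILL_GAS] * 5 + [AIR] + [LANDFILL_GAS] * 5
        events = detect_events(_records(labels), min_duration_min=10, max_gap=2)
        assert len(events) == 1 and events[0].duration_min == pytest.approx(11.0)

    def test_long_interruption_splits_events(self):
        labels = [LANDFILL_GAS] * 10 + [AIR] * 5 + [LANDFILL_GAS] * 10
        events = detect_events(_records(labels), min_duration_min=10, max_gap=2)
        assert len(events) == 2

    def test_events_never_overlap_and_durations_bounded(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([AIR, LANDFILL_GAS, FRESH_WASTE], size=200, p=[0.5, 0.3, 0.2])
        recs = _records(list(labels))
        events = detect_events(recs, min_duration_min=5, max_gap=1)
        events.sort(key=lambda e: e.start)
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
        total_nonair = sum(lab != AIR for lab in labels)
        assert sum(e.duration_min for e in events) <= total_nonair + 2 * len(events)


class TestDetectionFrequencies:
    def test_constructed_mix(self):
        labels = [AIR] * 975 + [FRESH_WASTE] * 10 + [LANDFILL_GAS] * 15
        freq = detection_frequencies(_records(labels))
        assert freq[AIR] == pytest.approx(97.5)
        assert freq[FRESH_WASTE] == pytest.approx(1.0)
        assert freq[LANDFILL_GAS] == pytest.approx(1.5)

    def test_all_air(self):
        freq = detection_frequencies(_records([AIR] * 10))
        assert freq == {AIR: 100.0}


class TestClassifyStream:
    def test_all_baseline_stream_is_all_air(self, fitted_models):
        _, model_a, _ = fitted_models
        params = simulate.fenceline_params(seed=3)
        sc = simulate.ScenarioParams(
            fenceline=params, receptor=simulate.receptor_params(4),
            episodes=[], duration_s=4 * 3600.0,
        )
        frame, *_ = simulate.simulate_monitoring_scenario(sc, seed=3)
        recs = classify_stream(model_a, frame, window_s=600.0)
        assert recs and all(r.label == AIR for r in recs)

    def test_scenario_episodes_recovered(self, fitted_models):
        """>= 90% of scheduled episode windows carry the right class."""
        _, model_a, _ = fitted_models
        sc = simulate.default_scenario(3)
        frame, *_ , gt = simulate.simulate_monitoring_scenario(sc, seed=9)
        recs = classify_stream(model_a, frame, window_s=600.0)
        by_t = {r.timestamp: r for r in recs}
        hits = total = 0
        for ep in gt.episodes:
            for t, r in by_t.items():
                if ep.start_s <= t and t + 600.0 <= ep.end_s:
                    total += 1
                    hits += r.label == ep.class_label
        assert total > 0 and hits / total >= 0.9

    def test_calibration_gap_yields_no_records(self, fitted_models):
        _, model_a, _ = fitted_models
        params = simulate.fenceline_params(seed=3)
        sc = simulate.ScenarioParams(
            fenceline=params, receptor=simulate.receptor_params(4),
            episodes=[], duration_s=3 * 3600.0,
        )
        frame, *_ = simulate.simulate_monitoring_scenario(sc, seed=5)
        # carve out a half-hour calibration pause
        keep = (frame.timestamps < 3600.0) | (frame.timestamps >= 5400.0)
        gapped = simulate.SensorFrame(
            frame.timestamps[keep],
            frame.channels.loc[keep].reset_index(drop=True),
            dict(frame.schema),
        )
        recs = classify_stream(model_a, gapped, window_s=600.0)
        in_gap = [r for r in recs if 3600.0 <= r.timestamp < 5400.0]
        assert in_gap == []
        assert len(recs) == 18 - 3  # 3 h of 10-min windows minus the pause


class TestWindFilter:
    def _wind(self, direction, speed=1.5, n=10, cadence=60.0):
        return [WindRecord(i * cadence, speed, direction) for i in range(n)]

    def test_compatible_provenance_kept(self):
        recs = _records([LANDFILL_GAS] * 3)
        kept, fp = wind_filter(recs, self._wind(0.0), source_bearing=0.0)
        assert len(kept) == 3 and fp == []

    def test_incompatible_provenance_false_positive(self):
        recs = _records([LANDFILL_GAS] * 3)
        kept, fp = wind_filter(recs, self._wind(135.0), source_bearing=0.0)
        assert kept == [] and len(fp) == 3

    def test_boundary_sector_closed(self):
        recs = _records([LANDFILL_GAS])
        kept, fp = wind_filter(recs, self._wind(45.0), source_bearing=0.0, half_angle=45.0)
        assert len(kept) == 1 and fp == []

    def test_air_passes_untouched_and_partition_holds(self):
        labels = [AIR, LANDFILL_GAS, "Unknown", FRESH_WASTE, LANDFILL_GAS]
        recs = _records(labels)
        kept, fp = wind_filter(recs, self._wind(90.0), source_bearing=0.0)
        assert {id(r) for r in kept} | {id(r) for r in fp} == {id(r) for r in recs}
        assert all(r.label in LANDFILL_CLASSES for r in fp)
        assert [r.label for r in kept if r.label not in LANDFILL_CLASSES] == [AIR, "Unknown"]

    def test_missing_wind_flagged_unassessable_but_kept(self):
        recs = _records([LANDFILL_GAS] * 2)
        with pytest.warns(UserWarning, match="no wind"):
            kept, fp = wind_filter(recs, [WindRecord(1e6, 1.5, 0.0)], source_bearing=0.0)
        assert len(kept) == 2 and kept[0].wind_status == "unassessable"


class TestOdorImpact:
    def test_low_frequency_acceptable(self):
        labels = [LANDFILL_GAS] * 24 + [AIR] * 9976
        impact, ok = odor_impact(_records(labels), "residential_mixed")
        assert impact == pytest.approx(0.24) and ok

    def test_limit_depends_on_area_type(self):
        labels = [LANDFILL_GAS] * 12 + [AIR] * 88
        impact, ok_res = odor_impact(_records(labels), "residential_mixed")
        _, ok_ind = odor_impact(_records(labels), "industrial_agricultural")
        assert impact == pytest.approx(12.0) and not ok_res and ok_ind

    def test_zero_impact_acceptable(self):
        impact, ok = odor_impact(_records([AIR] * 10), "residential_mixed")
        assert impact == 0.0 and ok


@pytest.fixture(scope="module")
def table():
    return datasets.load_event_table()


class TestEventTableAnalytics:
    """Analytics over the bundled monitoring event log."""

    def test_fourteen_fenceline_odor_events(self, table):
        assert (table["fenceline_class"] != AIR).sum() == 14

    def test_two_receptor_landfill_events_above_300(self, table):
        hits = table[table["receptor_class"].isin(LANDFILL_CLASSES)]
        assert len(hits) == 2
        assert hits["fenceline_conc"].min() >= 300
        assert set(hits["fenceline_class"]) == {LANDFILL_GAS}

    def test_fixed_threshold_300_counts(self, table):
        res = threshold_analysis(table, 300.0)
        assert res["fixed"]["alarm_event"] == 2
        assert res["fixed"]["alarm_event"] + res["fixed"]["alarm_no_event"] == 7

    def test_wind_conditioned_rule_removes_strong_wind_exceedance(self, table):
        res = threshold_analysis(table, 300.0)
        wind = res["wind_conditioned"]
        assert wind["alarm_event"] == 2 and wind["alarm_no_event"] == 0

    def test_infinite_threshold_no_exceedances(self, table):
        res = threshold_analysis(table, np.inf)
        assert res["fixed"]["alarm_event"] == 0
        assert res["fixed"]["alarm_no_event"] == 0

    def test_exceedances_monotone_in_threshold(self, table):
        prev = np.inf
        for thr in (100.0, 300.0, 500.0, 800.0):
            res = threshold_analysis(table, thr)
            n = res["fixed"]["alarm_event"] + res["fixed"]["alarm_no_event"]
            assert n <= prev
            prev = n


class TestCorrelateEvents:
    def test_scenario_pairing_matches_ground_truth(self, fitted_models):
        _, model_a, _ = fitted_models
        seed = 9
        sc = simulate.default_scenario(3)
        fence, rec, wind, gt = simulate.simulate_monitoring_scenario(sc, seed=seed)
        from odormon.classify import fit_stepwise_linear
        from odormon.features import build_training_set, extract_features

        rs, rf = simulate.simulate_training_campaign(sc.receptor, seed + 1)
        rfvs = [extract_features(f, sample_id=s.sample_id) for s, f in zip(rs, rf)]
        rclf = fit_stepwise_linear(build_training_set(rs, rfvs))
        frecs = classify_stream(model_a, fence, "fenceline", window_s=600.0)
        rrecs = classify_stream(rclf, rec, "receptor", window_s=600.0)
        fev = detect_events(frecs)
        rev = detect_events(rrecs)
        table = correlate_events(fev, rev, wind)
        assert len(fev) == len(gt.episodes)
        paired = table[table["receptor_class"] != AIR]
        assert len(paired) == sum(gt.receptor_detected)
        for (_, row), ep in zip(table.iterrows(), gt.episodes):
            assert row["fenceline_class"] == ep.class_label

    def test_unmatched_receptor_event_reported_against_air(self):
        rev = [monitor.OdorEvent("receptor", LANDFILL_GAS, 0.0, 30.0)]
        table = correlate_events([], rev, [])
        assert len(table) == 1
        assert table.iloc[0]["fenceline_class"] == AIR
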