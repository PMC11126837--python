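"""Two-site monitoring: fenceline detections, receptor events, wind
filtering and warning-threshold analysis.

Simulates 20 hours of parallel fenceline and receptor streams with a
schedule of emission episodes and wind conditions, classifies both streams,
aggregates detections into odor events, and correlates the two sites —
ending with the fixed vs wind-conditioned alarm-threshold comparison.
"""

from odormon import monitor, simulate
from odormon.classify import KnnClassifier, fit_stepwise_linear, select_k
from odormon.features import build_training_set, extract_features
from odormon.quantify import fit_double_step

SEED = 9

sc = simulate.default_scenario(SEED)
fence, receptor, wind, truth = simulate.simulate_monitoring_scenario(sc, SEED)
print(f"scenario: {len(truth.episodes)} scheduled episodes, "
      f"{sum(truth.receptor_detected)} reach the receptor by construction\n")


def train(params, seed):
    samples, frames = simulate.simulate_training_campaign(params, seed)
    fvs = [extract_features(f, sample_id=s.sample_id) for s, f in zip(samples, frames)]
    return build_training_set(samples, fvs)


ts = train(sc.fenceline, SEED)
k, _ = select_k(ts, seed=SEED)
model_a = fit_double_step(ts, KnnClassifier.fit(ts, k), seed=SEED)
receptor_clf = fit_stepwise_linear(train(sc.receptor, SEED + 1))

fence_recs = monitor.classify_stream(model_a, fence, "fenceline", window_s=600.0)
rec_recs = monitor.classify_stream(receptor_clf, receptor, "receptor", window_s=600.0)
print("fenceline detection frequencies (% of monitoring):",
      {k: round(v, 2) for k, v in monitor.detection_frequencies(fence_recs).items()})

kept, false_pos = monitor.wind_filter(rec_recs, wind, sc.source_bearing_deg,
                                      sc.sector_half_angle_deg)
impact, acceptable = monitor.odor_impact(kept, "residential_mixed")
print(f"receptor odor impact after wind filtering: {impact:.2f}% "
      f"({'acceptable' if acceptable else 'NOT acceptable'} vs the 10% odor-hour limit; "
      f"{len(false_pos)} false positives excluded)\n")

fence_events = monitor.detect_events(fence_recs)
rec_events = monitor.detect_events(kept)
table = monitor.correlate_events(fence_events, rec_events, wind)
print(table.to_string(index=False))

thr = monitor.threshold_analysis(table, 300.0, sc.source_bearing_deg,
                                 sc.sector_half_angle_deg)
print(f"\nfixed 300 ou_eq threshold: {thr['fixed']}")
print(f"wind-conditioned threshold: {thr['wind_conditioned']}")
print("\nA fixed fenceline alarm fires on episodes the wind never carries to"
      " the receptor; conditioning the alarm on a compatible, non-strong wind"
      " removes those false alarms without losing any alarmed receptor event."
      " (One genuine receptor event sits below the 300 ou_eq threshold under"
      " either rule — no fixed concentration cut captures everything.)")
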