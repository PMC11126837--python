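# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `odormon`.

## The double-step quantification model

Let x ∈ ℝᵖ be the feature vector of one analysis (two features per sensor
channel, see below), autoscaled with the training mean and SD. The
double-step model ("model A") is

1. **classification**: ĉ = classifier(x), over {Air, Fresh Waste,
   Landfill Gas, Leachate};
2. **quantification**: if ĉ = Air no concentration is emitted; otherwise
   ŷ = α_ĉ + x·β_ĉ with (α_ĉ, β_ĉ) a PLS regression of y = log₁₀ C fitted
   on the training rows of class ĉ only, and Ĉ = 10^ŷ, reported in
   *equivalent* odor units (ou_eq) to keep instrument estimates
   terminologically distinct from panel-measured ouE/m³.

The baseline ("model B") is a single PLS regression fitted on all odorous
training rows, class ignored. The premise: sources of different chemical
composition give different array fingerprints at equal odor concentration,
so the global regression is structurally confounded; routing by class
removes the confound at the cost of (a) needing enough training data per
class and (b) propagating classification errors into quantification.
Quantification is therefore only meaningful at or above the lower
classification limit, and the model-comparison statistics are computed on
samples above it.

Log₁₀ concentration is the regression target throughout: it linearises the
concentration–response relation of the sensors, compresses the wide dynamic
range of odor concentrations, and makes agreement statistics multiplicative
(see Bland–Altman below). Predictions with ŷ < 0 (below 1 ou_eq) are
clipped to 1 and flagged; a log-scale model extrapolates absurdly near
baseline and those values carry no information beyond "at baseline".

## Features

Each channel contributes a steady-state **level** (mean over the trailing
50% of the analysis window) and a baseline-relative **delta** (level minus
the pre-exposure baseline, the mean of the leading 20%). MOS resistances
are mapped to log₁₀ ohm first — MOS response is a power law in analyte
concentration, so log resistance is the scale on which linear models make
sense; electrochemical (ppm), temperature and humidity channels stay in
native units. All features are autoscaled (center, unit variance) before
PCA, k-NN and PLS alike, because the units are incommensurable.

For monitoring streams there is no clean pre-exposure segment; the baseline
is the per-channel **median over a trailing 2 h context**. The median is
unbiased on clean air and robust while episodes occupy less than half the
context. (An asymmetric low/high quantile was rejected: it shifts every
clean-air window's deltas toward an apparent weak response — MOS down, EC
up — and produces spurious low-concentration detections.)

## PLS

PLS is implemented as single-response NIPALS (PLS1). With one response the
NIPALS inner iteration converges in a single pass — the weight vector is
exactly X'y normalised — so the decomposition is closed-form,
deterministic, and needs no convergence tolerance in practice. The X block
is centered inside each fit in addition to the global autoscaling: a class
subset of a globally scaled matrix has a non-zero mean, and NIPALS requires
centered blocks. The implementation is verified against an independent PLS
implementation to 1e-15 and reduces exactly to OLS at full rank.

Component counts are chosen by 10-fold cross-validated RMSEP (seeded,
shuffled folds; ties to the smaller count) per class for model A and
globally for model B, and can be pinned via configuration to replicate a
previously selected setup. Rank-deficient requests fail loudly, naming the
achievable count.

Residual diagnostics report Shapiro–Wilk normality, Pearson correlations of
residuals with each predictor and with fitted values, a heteroscedasticity
slope test (squared residuals on fitted values) and the lag-1
autocorrelation, each flagged at α = 0.05; exactly-zero residual vectors
are reported as degenerate rather than tested.

## Classifiers

*k-NN* (fenceline): Euclidean distance on autoscaled features; k odd, chosen
by stratified 10-fold CV accuracy with ties toward small k; residual vote
ties broken by the smaller mean neighbour distance, making predictions
deterministic. *Stepwise-linear* (receptor): per class a one-vs-rest linear
indicator regression built by bidirectional p-value stepwise selection
(defaults p_enter = 0.05 < p_remove = 0.10), with an explicit rank guard —
pseudo-inverse fitting would otherwise split a coefficient across exactly
collinear columns and report both as significant. Accuracy indexes
(detection = odor/no-odor, classification = full label) carry Wilson 95%
intervals, which behave well at the small n of field campaigns; the
interval endpoints are exact (0/100%) at k = 0 and k = n.

## Detection and classification limits

The "neutrality" of clean air is operationalised as a Mahalanobis envelope:
air feature vectors are standardised by the air per-feature SD (mixed units
would otherwise dominate the covariance shrinkage target), a Ledoit–Wolf
regularised covariance is fitted, and the envelope is the 99th percentile
of the air self-distances. The LDL of a class is the lowest tested dilution
level from which upward every replicate exceeds the envelope; the LCL
additionally requires correct classification. Limits at the lowest tested
level are flagged censored; series that pass low but fail higher are
flagged non-monotone and the limit is set above the last failure.

## Agreement with dynamic olfactometry

Differences are d = log₁₀(predicted) − log₁₀(reference); the direction is
fixed so that a negative bias means the instrument under-reads. Bias,
SD (n−1), LoA = bias ± z·SD with z = 1.96 (the normal quantile — this is
the classical Bland–Altman limit, configurable); CI of the bias via
SE = SD/√n and of each LoA via the classical approximation SE = SD·√(3/n).
10^LoA are the multiplicative factors; the EN 13725-style acceptance takes
max(10^upper, 10^−lower) ≤ 3, boundary inclusive. Note the strictness: a
lower factor printed as "0.3x" reads as within factor 3, but 1/0.305 = 3.28
fails the strict rule — the package applies the rule literally and reports
the margin. A Shapiro–Wilk gate (p > 0.05) marks, but does not abort,
analyses with non-normal differences. CI-coverage checks use closed
intervals.

## Monitoring analytics

Streams are processed in fixed windows (default 10 min); windows containing
a data gap longer than two sampling periods (e.g. the receptor's periodic
automatic calibration) yield no record rather than an interpolated one.
Events are maximal runs of one non-Air class tolerating ≤ 2 interrupting
windows, kept at ≥ 10 min (matching the event log's granularity);
frequencies are percentages of non-gap windows. Wind is handled in the
meteorological provenance convention (degrees FROM, 0 = North); a receptor
landfill detection is compatible with the source when the provenance lies
within ± 45° (closed sector) of the source bearing — the sector width is a
design choice, "incompatible direction" having no standard quantification —
and incompatible detections are excluded as false positives from the
odor-impact figure, which is compared with the TA-Luft odor-hour limits
(10% residential/mixed, 15% industrial/agricultural). Fenceline and
receptor events are paired by interval overlap. The warning-threshold
analysis counts alarm/event confusions for a fixed concentration threshold
(alarm iff fenceline concentration ≥ threshold) and for a wind-conditioned
rule (additionally: compatible sector and non-strong wind). Strong wind
suppresses receptor transport only in that rule and in the simulator, never
as a hard filter on observations.

## Synthetic-data generator

The study's instrument data are confidential, so the generator defines the
package's test conditions. Channel level (on the feature scale: log₁₀ ohm
for MOS, ppm for electrochemical) is

  level_j(t) = b0_j + γ_j·(RH − RH₀) + b_cj·log₁₀(C / C_ref)·r(t) + ε_j,

with additive Gaussian noise ε_j, exponential rise r(t) (τ = 30 s), and
the response term zeroed below the channel's detection floor. Defaults
emulate the two instruments: a fenceline unit (4 MOS + H₂S/NH₃
electrochemical channels, 10 s sampling, floors at 50 ouE/m³) and a more
sensitive receptor unit (6 MOS, 60 s sampling, floors at 20 ouE/m³).
Fingerprint slope vectors are pairwise well-separated (cosine < 0.95);
per-class training ranges are Fresh Waste 50–310, Landfill Gas 60–700,
Leachate 50–620 ouE/m³, with 8/10/10 source samples per class, 3 dilutions
each, plus 24 ambient-air analyses — the campaign scale of a realistic
one-month deployment. The monitoring scenario schedules emission episodes
with per-episode wind (AR(1) direction wander around the scheduled
provenance, categorical speed); an episode reaches the receptor iff the
sector is compatible, the wind is not strong, and the 10× transport
dilution clears the receptor floor. Everything is driven by explicit seeds
and is bit-reproducible.

What the generator does **not** emulate — and hence what green tests do not
show about real data: sensor drift and aging, cross-humidity nonlinearity,
transient shape variability, overlapping mixed-class plumes, atmospheric
dispersion physics (transport is a fixed dilution factor with no delay),
and non-Gaussian noise. On this clean log-linear world the global model is
only mildly handicapped (a linear map from features to log C exists when
the class directions are independent), so the double-step advantage shows
up as a consistent but modest held-out RMSEP edge across seeds; the bundled
field dataset shows the full-size effect (factor 2 vs factor 4 agreement).

## Problem sizes and determinism

The test suite and the acceptance script run campaigns of 108 analyses
(84 odorous + 24 air), dilution probes of 2–3 replicates per level, a 20 h
monitoring scenario, and 20-seed model comparisons; these sizes give stable
statistics for every asserted property while keeping a full run in tens of
seconds. All stochastic tests fix their seeds; model files round-trip
bit-identically through versioned JSON.

## Known limitations

- The stepwise classifier offers no formal error control across the
  selection path (p-values are nominal, as is conventional).
- The LCL/LDL scan assumes the tested grid brackets the limit; a grid
  entirely above the floor yields a censored value, not an extrapolation.
- The stream-baseline median degrades when odor episodes occupy more than
  half of the trailing context (persistent emissions); a longer context or
  an explicit clean-air reference should be configured for such sites.
- Event pairing by interval overlap has no notion of transport delay; at
  2 km and weak wind the offset can reach tens of minutes, which the
  default 10-min windows absorb only partially.
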