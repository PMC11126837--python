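"""Bland-Altman agreement between instrument odor estimates and dynamic
olfactometry, in log10 space.

Dynamic olfactometry — the reference sensory method — carries an uncertainty
of roughly a factor of 3, so agreement is assessed on paired *ratios*:
differences of log10 concentrations.  The bias and the limits of agreement
(bias +/- z*SD, z = 1.96) then exponentiate to multiplicative factors
(10^LoA), directly comparable with the EN 13725 acceptability criterion that
two consecutive odor measurements agree within a factor 3.

Difference direction is fixed as predicted minus reference: a negative bias
means the instrument under-reads relative to the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AIR, OdorSample, ValidationError

__all__ = [
    "AgreementResult",
    "log_differences",
    "normality_gate",
    "bland_altman",
    "factor_acceptance",
    "ci_coverage",
]


@dataclass
class AgreementResult:
    """Bland-Altman summary in log10 units with multiplicative factors."""

    n: int
    differences: np.ndarray
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    factor_lower: float
    factor_upper: float
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    normality_pass: bool | None = None

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValidationError("limits of agreement must bracket the bias")


def log_differences(predicted, reference) -> np.ndarray:
    """Paired log10 differences d_i = log10(pred_i) - log10(ref_i)."""
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValidationError("need equal-length 1-d arrays with n >= 3")
    for i, (p, r) in enumerate(zip(pred, ref)):
        if not (p > 0 and r > 0):
            raise ValidationError(f"non-positive value in pair {i}: pred={p}, ref={r}")
    return np.log10(pred) - np.log10(ref)


def normality_gate(d) -> tuple[float, float, bool]:
    """Shapiro-Wilk test of the differences.

    Bland-Altman limits assume approximately normal differences; a failing
    gate (p <= 0.05) does not abort the analysis but marks the result."""
    d = np.asarray(d, dtype=float)
    if not 3 <= len(d) <= 5000:
        raise ValidationError(f"Shapiro-Wilk defined for 3 <= n <= 5000, got {len(d)}")
    if np.ptp(d) == 0:
        raise ValidationError("differences are constant; normality test degenerate")
    res = stats.shapiro(d)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue > 0.05)


def bland_altman(d, z: float = 1.96, ci_level: float = 0.95) -> AgreementResult:
    """Bland-Altman statistics of log10 differences.

    bias = mean(d); sd = sample SD (n-1 denominator); LoA = bias +/- z*sd.
    The bias CI uses SE = sd/sqrt(n); each LoA CI uses the classic
    approximation SE = sd*sqrt(3/n).  Multiplicative factors are 10^LoA.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValidationError("need at least 3 differences")
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - z * sd, bias + z * sd
    zc = float(stats.norm.ppf(0.5 + ci_level / 2))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    try:
        w, p, ok = normality_gate(d)
    except ValidationError:
        w = p = None
        ok = None
    return AgreementResult(
        n=n,
        differences=d,
        bias=bias,
        sd=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        bias_ci=(bias - zc * se_bias, bias + zc * se_bias),
        loa_lower_ci=(loa_lo - zc * se_loa, loa_lo + zc * se_loa),
        loa_upper_ci=(loa_hi - zc * se_loa, loa_hi + zc * se_loa),
        factor_lower=float(10.0 ** loa_lo),
        factor_upper=float(10.0 ** loa_hi),
        shapiro_w=w,
        shapiro_p=p,
        normality_pass=ok,
    )


def factor_acceptance(result: AgreementResult, max_factor: float = 3.0) -> tuple[bool, float]:
    """EN 13725-style acceptance: both multiplicative limits within
    ``max_factor`` of unity (boundary inclusive).  Returns (pass, margin)
    where margin = max_factor minus the worse of the two factors."""
    worst = max(result.factor_upper, 1.0 / result.factor_lower)
    # boundary inclusive, tolerant of float round-trip through 10**log10
    return worst <= max_factor * (1 + 1e-12), float(max_factor - worst)


def ci_coverage(
    predictions: dict[str, float], samples: list[OdorSample]
) -> pd.DataFrame:
    """Flag which predictions fall inside the olfactometry 95% CI.

    ``predictions`` maps sample_id to estimated concentration.  Samples
    without a CI are excluded with a warning column; the interval is closed
    (a prediction exactly at a bound counts as within)."""
    rows = []
    for s in samples:
        if s.class_label == AIR:
            continue
        pred = predictions.get(s.sample_id)
        if pred is None:
            continue
        if s.ci_low is None:
            rows.append({"sample_id": s.sample_id, "class": s.class_label,
                         "prediction": pred, "within": None, "note": "no CI"})
            continue
        rows.append({
            "sample_id": s.sample_id,
            "class": s.class_label,
            "prediction": pred,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "within": bool(s.ci_low <= pred <= s.ci_high),
            "note": "",
        })
    return pd.DataFrame(rows)
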