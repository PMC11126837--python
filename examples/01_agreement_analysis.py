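"""Bland-Altman agreement of e-nose odor estimates with dynamic olfactometry.

Loads the bundled field-validation dataset (12 odorous samples measured in
parallel by a human olfactometry panel and by the fenceline e-nose under two
quantification models), tests the log differences for normality, and
computes bias and limits of agreement in log10 space, expressed as
multiplicative factors.
"""

from odormon import datasets
from odormon.agreement import (
    bland_altman,
    ci_coverage,
    factor_acceptance,
    log_differences,
)

df = datasets.load_validation_table()
ref = df["conc_oue"].to_numpy(float)
print(f"{len(df)} validation samples, olfactometry range "
      f"{ref.min():.0f}-{ref.max():.0f} ouE/m3\n")

for tag, col in (("double-step model A", "pred_model_a"),
                 ("global model B", "pred_model_b")):
    d = bland_altman(log_differences(df[col].to_numpy(float), ref))
    ok, margin = factor_acceptance(d, 3.0)
    print(f"{tag}:")
    print(f"  Shapiro-Wilk p = {d.shapiro_p:.2f} "
          f"({'normality not rejected' if d.normality_pass else 'non-normal!'})")
    print(f"  bias {d.bias:+.2f} log10 units "
          f"(instrument reads {'below' if d.bias < 0 else 'above'} the panel on average)")
    print(f"  limits of agreement [{d.loa_lower:+.2f}, {d.loa_upper:+.2f}] "
          f"-> factors {d.factor_lower:.2f}x / {d.factor_upper:.2f}x")
    print(f"  EN 13725 factor-3 criterion: {'PASS' if ok else 'FAIL'} "
          f"(margin {margin:+.2f})\n")

cov = ci_coverage(datasets.validation_predictions("b"), datasets.validation_samples())
outside = cov[cov["within"] == False]  # noqa: E712
print("global-model predictions outside the olfactometry 95% CI:")
print(outside[["sample_id", "class", "prediction", "ci_low", "ci_high"]].to_string(index=False))
print("\n95% of double-step estimates agree with the panel within a factor"
      " ~2; the global model spreads to a factor ~4, driven by Fresh Waste"
      " samples quantified with the wrong fingerprint weighting.")
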