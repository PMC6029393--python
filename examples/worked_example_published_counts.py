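"""Recompute published operating characteristics from their 2x2 counts.

The clinical study behind the default panel printed, for the 6-of-19
marker-count threshold: 34 of 38 DRE cases test-positive and 35 of 49 DRE
controls test-negative (30/32 and 25/35 for first-void urine).  Feeding those
counts through the diagnostics module reproduces the printed sensitivity,
specificity, PPV and NPV, and the Wilson intervals match the printed per-assay
CIs.
"""

from methpanel import ConfusionCounts, diagnostic_metrics, fisher_z_ci, proportion_ci
from methpanel.diagnostics import round_half_up

for name, counts in {
    "DRE": ConfusionCounts(tp=34, fn=4, tn=35, fp=14),
    "FV": ConfusionCounts(tp=30, fn=2, tn=25, fp=10),
}.items():
    row = diagnostic_metrics(counts)
    print(f"{name}: sensitivity {row.sensitivity.value:.2f} "
          f"(95% CI {row.sensitivity.ci_low:.2f}-{row.sensitivity.ci_high:.2f}), "
          f"specificity {row.specificity.value:.2f}, "
          f"PPV {round_half_up(row.ppv.value):.2f}, NPV {round_half_up(row.npv.value):.2f}")

# Wilson score interval for one assay's sensitivity (23 positive of 38 cases)
lo, hi = proportion_ci(23, 38, "wilson")
print(f"ADCY4 DRE sensitivity 23/38 = {23/38:.2f}, Wilson 95% CI ({lo:.2f}, {hi:.2f})")

# Fisher-z CI for the correlation between CAPRA grade and average methylation
lo, hi = fisher_z_ci(0.649, n=35)
print(f"CAPRA correlation r = 0.649 at n = 35: Fisher-z 95% CI ({lo:.3f}, {hi:.3f})")

print("\nA patient whose urine methylates >= 6 of the 19 markers would be "
      "referred to biopsy; the NPV row says how safe a negative call is.")
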