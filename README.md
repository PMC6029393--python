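# methpanel

Diagnostic analysis of multi-marker DNA-methylation panels assayed by
methylation-specific qPCR (MS-qPCR), built around a 19-CpG-island / 24-assay
urine panel for prostate-cancer detection.

## The problem

PSA screening refers many men to prostate biopsies that come back negative.
Aberrant CpG-island methylation is an early, cancer-specific signal that is
detectable in the cell-free and cellular DNA of urine — collected either after
a digital rectal exam (DRE, prostate-enriched) or as a plain first morning
void (FV).  A panel of methylation markers read out by MS-qPCR can act as a
secondary test: refer to biopsy only when enough markers are methylated.

`methpanel` is for biomarker and biostatistics groups evaluating such panels.
It takes raw qPCR quantification cycles (Cq) to a full diagnostic evaluation:

1. **ingest** — Cq values become transformed methylation levels
   `L = max(0, cutoff − Cq)` with a 32-cycle positivity cutoff, so `L = 0`
   means no amplification and larger `L` means more methylated template;
   duplicate wells are aggregated (default: lowest Cq).
2. **scoring** — markers probed by two assays (forward and
   reverse-complement designs on the same island) are merged by the highest
   level detected; each sample gets the count of positive markers
   `n = #{m : L_m > 0}` ("n-of-19") and the average methylation
   `(1/19) Σ_m L_m`; the default classifier calls a sample positive when
   `n ≥ 6`.
3. **diagnostics** — 2×2 cross-tabulations against biopsy outcome with
   sensitivity, specificity, PPV, NPV and binomial CIs (Wilson score by
   default; normal, Clopper–Pearson and seeded bootstrap available), per
   assay and across every count threshold.
4. **roc** — tie-corrected Mann–Whitney AUC
   `[#(case > control) + ½·#(ties)] / (n₁n₀)`, empirical ROC curves, and the
   exhaustive AUC of every k-marker sub-panel (C(19,6) = 27,132 subsets run
   in seconds).
5. **compare** — paired DRE-vs-FV analyses: per-marker paired t-tests, an
   exact binomial (McNemar-style) comparison of the two binary tests on their
   discordant pairs, concordance, Wilcoxon rank-sum by risk group, and
   Pearson correlation with Fisher-z CIs against CAPRA risk grade.
6. **synth** — a seeded synthetic-cohort generator calibrated to the panel's
   published per-assay positivity rates, emitting raw Cq tables so the whole
   pipeline can be exercised end to end without patient data.

## Worked example

`python examples/worked_example_published_counts.py` feeds the published
2×2 counts of the panel's clinical study (34/38 DRE cases test-positive,
35/49 controls test-negative at the 6-of-19 threshold; 30/32 and 25/35 for
FV) through the diagnostics module:

```
DRE: sensitivity 0.89 (95% CI 0.76-0.96), specificity 0.71, PPV 0.71, NPV 0.90
FV: sensitivity 0.94 (95% CI 0.80-0.98), specificity 0.71, PPV 0.75, NPV 0.93
ADCY4 DRE sensitivity 23/38 = 0.61, Wilson 95% CI (0.45, 0.74)
CAPRA correlation r = 0.649 at n = 35: Fisher-z 95% CI (0.403, 0.808)
```

A sensitivity of 0.89 at specificity 0.71 with NPV 0.90 means nine of ten men
called test-negative truly had a negative biopsy — the operating point that
makes the panel useful for avoiding unnecessary biopsies.

The other examples generate a synthetic cohort and run the rest of the
machinery (`synthetic_cohort_pipeline.py`, `subset_auc_enumeration.py`,
`paired_dre_fv_comparison.py`).  Enumerating all k-marker sub-panels on a
synthetic cohort prints, for instance:

```
 k  subsets  mean AUC      sd    min    max
 2      171     0.762   0.072  0.577  0.940
 6    27132     0.891   0.045  0.716  0.991
```

— mean AUC rises and spread shrinks as panels grow, because larger panels
buffer the fragment-sampling noise of urine DNA.

There is also a thin CLI (`methpanel synth|ingest|score|diagnostics|run`),
e.g. `methpanel run --synthetic --out report/ --seed 1`, which writes the
full report bundle (assay and threshold performance tables, ROC points,
subset AUCs, paired and group comparisons, QC report, manifest) as TSV/JSON.

## Layout

- `src/methpanel/` — the library (`panel`, `ingest`, `scoring`,
  `diagnostics`, `roc`, `compare`, `synth`, `pipeline`, `cli`, `study`,
  `calibration`).
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `examples/` — one narrative script per capability.
- `tests/` — pytest suite (unit, property-based, end-to-end).
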