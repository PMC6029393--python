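# Methods

## Cq transform and positivity

MS-qPCR reports a quantification cycle Cq per well; fewer cycles means more
methylated template.  The analysis scale is the transformed level
`L = cutoff − Cq` for amplified wells with `Cq < cutoff`, and `L = 0` for
no amplification or `Cq ≥ cutoff`.  The default cutoff is 32 cycles (the
run length of the assays the default panel was validated with), giving the
0–15 range observed in the calibration study; levels above 15 (Cq < 17) are
legal and logged rather than clamped, since 0–15 is an observed range, not a
hard bound.

A well with Cq exactly at the cutoff maps to `L = 0` and is therefore
negative under the `L > 0` positivity rule.  The alternative reading (cutoff
itself positive) would create a "positive" marker with zero level, which
contradicts every downstream rule that treats 0 as absence; we use the
consistent convention and note it here because published descriptions of
such cutoffs are often ambiguous.

Duplicate wells are aggregated per assay × sample, by default keeping the
highest level (lowest Cq).  This matches the union philosophy of the
dual-assay merge: the strongest detection is the best evidence about the
island's methylation state.  `mean` and `mean_of_positives` are available
for sensitivity analyses.  Assays absent from an otherwise present sample
are imputed as level 0 with a per-sample warning (absence of amplification
is the 0 state); samples can instead be excluded wholesale
(`missing_assay="exclude"`).  Sample-level DNA-yield QC happens upstream of
this package; recovery-control assays (an imprinted promoter for the short
bisulfite condition, a degenerate-primer control for the long one) are
reported per sample in the QC table and never enter scores.

## Scores and classifier

Five markers carry two assays (forward and reverse-complement designs on
different portions of the island); marker level = max of the two assay
levels, so a marker is positive iff either assay is (union rule).  The
sample score `n_positive` counts markers with level > 0; `avg_methylation`
is the mean of the 19 merged marker levels — dividing the merged values
rather than the 24 raw assay values avoids double-weighting dual-assay
islands.  The classifier calls a sample positive when `n_positive ≥ t`,
default `t = 6`, the threshold chosen in the calibration study for a target
specificity of 70% (a deliberately modest target: prostate biopsy itself
misses cancers, so 70% against biopsy corresponds to substantially higher
specificity against truth).

## Diagnostics and confidence intervals

Sensitivity, specificity, PPV and NPV come from exact integer 2×2 counts;
zero-denominator metrics are explicit nulls with a reason code, never 0.
Binomial CIs default to the Wilson score interval, which reproduces the
calibration study's printed per-assay intervals at 2 decimal places.  The
study's per-threshold table appears to use a different (unstated, possibly
bootstrap) interval method; interval methods are therefore configurable
(wilson / normal / clopper-pearson / seeded percentile bootstrap with 2,000
resamples) and interval values are not treated as exact reproduction
targets.  Report rounding is half-up to 2 dp; machine outputs keep full
precision.

## ROC and subset enumeration

AUC is the tie-corrected Mann–Whitney statistic computed via midranks,
identical to the trapezoidal area under the empirical ROC curve (asserted to
1e-12 in tests; curve points come from scikit-learn with
`drop_intermediate=False`).  Sub-panel evaluation scores each sample by the
count of positive markers within the subset; enumeration over all C(19, k)
subsets (k ≤ 6 by default) is exact and lexicographic, vectorized as a
boolean-matrix product followed by column-wise midranks.  PSA curves drop
patients with missing PSA (count logged).

## Paired and group comparisons

- Per-marker DRE−FV differences: paired t-test with a t-based 95% CI — the
  calibration study reports symmetric CIs around a mean difference, which is
  what a paired t produces.  Zero-variance differences yield a degenerate
  (point) CI and are flagged.
- Two binary tests on the same patients: the difference in sensitivity is
  assessed among cases (specificity among controls) with an exact binomial
  test conditioned on the discordant pairs — p doubles the smaller tail of
  Binomial(b + c, ½), capped at 1, so balanced discordants give p = 1 — and
  a Wald CI with paired variance (b + c − (b−c)²/n)/n².
- Wilcoxon rank-sum: exact null distribution when the pooled sample has ≤ 20
  observations and no ties; otherwise normal approximation with midranks,
  tie-corrected variance and continuity correction.
- Pearson correlation with Fisher-z CI `tanh(atanh r ± z/√(n−3))`; the CAPRA
  correlation uses the ordinal risk-group code among cases (raw CAPRA scores
  accepted when available).
- Group summaries (negative biopsy / CAPRA 1–2 / CAPRA ≥ 3) use type-7
  linear-interpolation quantiles, numpy's default, fixed and documented so
  box-plot tables are bit-reproducible.

## Synthetic cohort generator

The generator's defaults are the calibration study's conditions: 42 cases /
52 controls; per-assay positivity probabilities equal to the published DRE
proportions (cases: positives/cases; controls: 1 − negatives/controls);
per-patient sample availability (both/DRE-only/FV-only = 60/27/7 of 94);
PSA log-normal per group matched to the published medians and means
(6.4/7.1 cases, 5.2/5.6 controls); elevated-CAPRA fraction 20/35 among
cases.

Positivity is generated at marker level and split to assays.  For a
dual-assay marker with published union rate `u` and assay rates `a₁, a₂`,
detection given a positive marker uses the joint distribution on
{both, only-1, only-2} with marginals `dᵢ = aᵢ/u` and union 1 (feasible,
`d₁ + d₂ ≥ 1`, for every dual marker in both sample types), so assay-level
and marker-level rates are both reproduced exactly in expectation.

CAPRA risk shifts case positivity by `capra_effect` (default 0.8) in
log-odds between the low- and elevated-risk groups, recentered numerically
so the overall case marginal still equals the calibration probability —
burden increases with risk group without breaking parameter recovery.
Levels given positivity are truncated-normal on (0, 15] with mean 6 and
sd 3, rounded to 0.1 (a dispersed mid-range distribution consistent with a
semi-quantitative 0–15 readout; no published level distribution exists to
calibrate against).  FV marker states agree with the patient's DRE state
with probability 0.8 (a modeling choice — the real within-patient agreement
is not published) and are otherwise redrawn from the FV marginal, where
three markers known to be recovered less well from first-void urine (AOX1,
GFRA2, NEUROG3) are attenuated by the published FV/DRE rate ratios
(0.62/0.91/0.59).  Cohorts are emitted as duplicate-well Cq tables
(Cq = 32 − level, second replicate jittered upward) so tests exercise the
real ingest path; with no missingness the ingest+scoring round trip recovers
the generated states exactly.

**What the generator does not emulate.** Markers are conditionally
independent given case status and risk group.  Real methylation markers are
positively correlated within a patient (shared tumor burden, shared DNA
recovery), which lowers multivariate performance; consequently synthetic
full-panel AUCs (~0.95–0.97) exceed the ~0.87–0.92 observed clinically, and
synthetic control medians (~4) sit slightly above the observed 3.  Passing
tests on synthetic data therefore validate the *machinery* (calibration
recovery, monotonicity, enumeration, pairing), not clinical performance.
Single-marker quantities and the subset-AUC *trend* (mean up, spread down
with k) are faithful; absolute multi-marker AUC levels are optimistic.

## Numerical and design choices

- All randomness flows from one `numpy.random.default_rng(seed)`; no global
  state; fixture writes are byte-stable per seed.
- The panel is config-driven (YAML) with the 19-marker panel as the built-in
  default; `load_panel` enforces the 19/24 shape by default but accepts
  other panel sizes explicitly.  Assay aliases (e.g. two published labels
  for the same HEMK1 assay) are resolved on ingest.  The per-assay bisulfite
  condition grouping in the default config is placeholder QC metadata, not
  the published grouping.
- The exact rank-sum branch requires no ties because the exact Mann–Whitney
  null assumes continuity; identical multisets fall through to the
  tie-corrected normal path, which returns p = 1 by the continuity-corrected
  zero statistic.
- `enumerate_subset_aucs` batches subsets (4,096 at a time) to bound memory
  at study-scale cohorts.

## Limitations

- The original per-patient marker table is distributed only as a study
  supplement with no public accession; `methpanel.study.reproduce_study`
  implements the full re-analysis but ships unexercised against the real
  cohort (tested against synthetic tables in the same layout).
- Machine-learning panel selection (boosting, elastic net, cross-validated
  best-subset search) is out of scope: count-score subset enumeration covers
  panel-size questions without fitted models.
- No multiple-testing adjustment across markers (none is applied in the
  calibration study's tables); absolute copy-number quantitation and
  bisulfite batch normalization are out of scope — the assays are
  semi-quantitative.
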