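# Methods

## The measurement model

All statistics operate on a long-format table of morphometric values
keyed by subject, centre (scanner site), visit (repeat session on the
same scanner), hemisphere, and measure — optionally by sulcus label and
recognition algorithm for sulcus-wise measures. The design is assumed
fully crossed: every subject is scanned at every centre on every visit.
Subjects with any missing centre × visit × hemisphere cell are excluded
listwise per measure (no imputation), mirroring how repeated-scan
studies handle dropouts; the exclusions are reported in the design
summary and the report metadata.

Hemispheres are treated by default as within-cell replicates rather
than a design factor. Left and right values of a subject share all
scanner-related effects in the model, so the replicate treatment
provides within-cell replication that makes the three-way
subject×centre×visit component estimable. Per-hemisphere analysis is
available by filtering the table; sulcus-wise analyses always run per
hemisphere (one observation per cell) because left and right sulci of
the same label differ systematically in size.

For one measure the crossed random-effects ANOVA is

    y_scvh = μ + A_s + B_c + C_v + AB_sc + AC_sv + BC_cv + ABC_scv + ε_scvh

with all effects independent, zero-mean Gaussian with variances σ²_T.
The subject component σ²_A is the biological between-subject variance
the study wants to preserve; everything containing centre or visit is
nuisance.

## Variance-component estimation

For balanced data the components are estimated by the classical method
of moments: the ANOVA mean squares of all seven strata are computed
from the marginal-means decomposition, and the expected-mean-squares
(EMS) system of the fully random balanced model is solved exactly. The
EMS coefficient of σ²_T in E[MS_S] is n·(product of the levels of the
factors absent from T) whenever T's factor set contains S's, plus a
unit coefficient for the residual. With one observation per cell the
three-way interaction is confounded with the residual and reported
under `residual`.

Raw moment solutions can be negative; they are truncated at zero before
any reliability is formed (the classical convention), and the raw
values are kept alongside for transparency — the report writer logs a
warning whenever truncation fires.

REML estimation is available (`method="reml"`) through a crossed
variance-components mixed model (statsmodels `MixedLM`, one all-
encompassing group, each term a variance component) and is the route
for unbalanced data. The optimizer is warm-started at the truncated
moment solution and falls back through several optimizers keeping the
best REML criterion; without the warm start the default optimizer
frequently stalls on designs this small. For balanced data the two
estimators coincide exactly (to optimizer precision) whenever the
moment solution is admissible (all raw components ≥ 0); at boundary
solutions they are different estimators by construction — truncation
versus constrained joint optimization — and differ by small systematic
amounts (of order 0.05 on unit-scale components in our simulations).
The test suite asserts the exact equivalence on admissible tables and
bounds the unconditional paired means accordingly.

## The reliability statistic

    reliability(F) = (V_total − V_F) / V_total,  F ∈ {centre, visit}

with V_total the sum of all truncated components and V_F the sum of
σ²_F and every interaction containing F. Both centre:visit and (when
estimable) the three-way component count against **both** factors — a
literal reading of "the factor and its interactions". Values are
clamped to [0, 1] and graded with left-closed intervals: poor [0, 0.50),
moderate [0.50, 0.70), good [0.70, 0.90), excellent [0.90, 1], so every
value maps to exactly one grade (the conventional rule of thumb is
ambiguous at the cut points; 0.50 grades as moderate here).

Reliability ratios estimated from few degrees of freedom are biased
low: with only 3 centres (2 df for the centre mean square) the mean
estimated between-centre reliability at the default 13×3×2×2 design
sits ≈ 0.02 below its analytic value, and per-sulcus estimates (one
observation per cell, single hemisphere) further still. This is a
property of the plug-in ratio, not of the component estimates, which
are unbiased before truncation; it is why across-sulcus summaries
should be read comparatively (between algorithms, between field
strengths) rather than as absolute values.

When covariates are configured for the random model, the values are
first residualized against the pooled covariate slopes (grand mean
retained) and then decomposed; whether scanner-reliability studies
covariate-adjust their random models is typically unreported, so this
choice is recorded in the output metadata and can be disabled
(`residualize_covariates: false`).

Across-sulcus summaries are unweighted means over the analysed
sulcus × hemisphere pieces; sulci whose design collapses (fewer than
two complete subjects, degenerate variance) are skipped and listed.

## Scanner-effect ANCOVA

Fixed-effects model per measure: `value ~ subject + centre + visit +
centre:visit [+ covariates]`, covariates being hemisphere (brain)
volume for global measures and additionally GSI for sulcal measures.
Factors use sum-to-zero contrasts so that drop-one ("adjusted",
Type-III-like) tests of main effects remain meaningful with the
interaction present; on balanced designs without covariates adjusted
and sequential sums of squares coincide, and the suite asserts it.
F denominators always use the full-model residual mean square — no
quasi-F synthesis; a documented limitation, adequate for the
descriptive use these p-values get. Covariates are mean-centered
(stabilises the intercept, leaves F tests unchanged) and modelled
additively only. p-values are reported unadjusted for multiple testing
and formatted "< 0.001" below 0.001, else to 3 decimals.

## Image metrics

Bias-correction quality on a T1-like volume with WM/GM/CSF masks:

* **Coefficient of variation** within a mask: population (1/N) SD over
  mean of the masked grey levels (configurable `ddof`; masks are large,
  the distinction is immaterial but documented). Requires ≥ 10 voxels
  by default and a positive mean.
* **Peak (modal) grey level**: histogram over the mask's [1st, 99th]
  percentile range (outlier-resistant), 128 bins, moving-average
  smoothing over 3 bins, centre of the maximal bin, ties toward the
  lower grey level. All knobs sit in `PeakConfig`; a kernel-density
  mode would be a reasonable alternative estimator. The histogram mode
  of 10⁵ Gaussian samples at these defaults wanders a few bin widths
  (≈ 0.2 σ); widening the smoothing window trades bias for variance.
* **WM/GM contrast**: ratio of the WM to the GM peak; > 1 on T1-like
  images. Scale-invariant, as is the CoV.
* **Mask intersection** (voxelwise AND) lets two segmentation programs
  be compared on their common voxels without favouring either.

Metrics are computed over whichever mask is supplied; to follow the
whole-cerebrum convention, pass the union of both hemispheres' masks —
the suite asserts union-mask equality. Volumes are used on their native
grid; no resampling or registration.

## Synthetic generators

`simulate_morphometry` draws tables from the additive crossed model
above. Defaults mirror a 1.5 T multicentre cohort: 13 subjects ×
3 centres × 2 visits × 2 hemispheres, GM-volume grand mean 259 cm³,
components (subject 9, centre 1, visit 0.25, subject×centre 0.5,
residual 1) cm⁶ — dominant biological variance, a real but smaller
scanner effect, a small session effect. An 11 × 5 × 2 × 2 variant
mirrors a five-centre 3 T cohort. Optional fixed per-centre offsets
model systematic calibration differences; an optional brain-size
covariate has per-subject spread (default SD 40 cm³) plus per-scan
measurement noise (default SD 5 cm³ — without it the covariate would
be confounded with the subject factor). Sulcus-wise simulation runs
the same model independently per sulcus with per-sulcus grand means
drawn once (default N(900, 400²) mm², reflecting the large size
differences between sulci). One seed governs a draw; each term (and
each sulcus) gets its own hash-derived sub-stream, so enlarging the
design preserves shared draws. Ground truth (drawn effects, analytic
reliabilities) is returned alongside.

What the generator does **not** emulate: systematic left/right
asymmetry (hemispheres are exchangeable replicates here, unlike real
brains), non-Gaussian or heavy-tailed effects, correlations between
measures, and any dependence of variance on brain size. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to real-data violations of it.

`simulate_phantom` builds nested-sphere phantoms (WM core r ≤ 0.30,
GM shell to 0.55, CSF shell to 0.75 of the half-extent; default
48³ voxels) with tissue means 150/100/40, Gaussian noise (default
σ = 5), and a multiplicative bias field 1 + α·g(x) where g is a
normalized separable product of phase-shifted half-cosine profiles
spanning [−1, 1]. The phase shift puts a strong field gradient across
the central tissue regions — a centred symmetric profile is nearly
flat over the middle of the volume and would barely perturb the WM
core. α = 0 gives a bias-free phantom; masks are deterministic
functions of the geometry alone. No MR physics (TR/TE, partial volume,
Rician noise) is modelled.

## Numerical and design notes

* Estimated components are invariant to adding a constant to all values
  and scale as c² when values scale by c; reliabilities are invariant
  to both. Asserted in the suite.
* Degenerate inputs raise typed errors: unbalanced designs point to the
  REML option; single-level factors, saturated models (zero residual
  df or zero residual variance), empty designs, undefined reliabilities
  (V_total = 0) and empty masks all have dedicated exceptions.
* The report pipeline is a thin orchestrator: every number in its CSVs
  is reproducible by calling the module functions directly, outputs are
  byte-deterministic for identical inputs, and a manifest records the
  config, package version and SHA-256 of each input. Failures quarantine
  partial outputs instead of leaving a half-written report.
* Problem sizes in the test suite (200-table REML comparison, 500-table
  recovery, 2000-table null calibration, 48³ phantoms) were chosen so
  Monte-Carlo error is comfortably below the asserted tolerances while
  the whole suite runs in a couple of minutes on one core.

## Known limitations

* Moment estimation requires balance; Henderson-III style unbalanced
  moment estimators are not implemented (REML covers that case).
* No confidence intervals on reliabilities (a subject-level bootstrap
  would be the natural extension).
* Fixed-effects F tests use the residual denominator; under a random-
  effects truth the centre test is anticonservative for inference about
  the population of scanners — the p-values are descriptive, matching
  their intended use.
* Grades at the cut points follow the left-closed convention above;
  other conventions will disagree exactly at 0.50/0.70/0.90.
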