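# Methods

## The model

`ictaxis` operationalizes the location of a subject on a continuum between
impulsive and compulsive character, as screened through four self-report
instruments on the use/abuse of information and communication technologies
(ICT): the short UPPS-P impulsivity scale (20 items, 1–4), the OCDUS
adapted to ICT (12 items, 1–7, items 6 and 12 reverse-keyed), the PSI-20
prefrontal-symptom screening (20 items, 0–4), and the MULTICAGE-ICT
problematic-use screen (20 dichotomous items in five 4-item scales).

The axis is built in five steps:

1. **Scoring.** Each subscale is the sum of its item responses after
   reverse keys; the UPPS urgency and sensation-seeking subscales are
   additionally inverted at the scale level (s → LO+HI−s) so every
   subscale points toward higher impulsivity. Item reversal is an
   involution, and every theoretical range endpoint is attainable.
2. **Rescaling.** Every subscale is linearly mapped to 0 (theoretical
   minimum) … 100 (maximum).
3. **Outlier exclusion.** Squared Mahalanobis distances of the eight
   UPPS/OCDUS subscale scores, against the chi-square(8) quantile at
   1−α (α = 0.001 by default, threshold ≈ 26.12). The sample mean and
   (n−1) covariance are used; the filter is invariant under any
   invertible affine transform of the score block.
4. **Residualization.** Each of the eight subscales is regressed (OLS,
   both covariates jointly) on ordinal age and education band codes
   (1..6 and 1..5 over the collection bands); raw residuals are divided
   by their (n−1) SD, giving columns with mean exactly 0 and SD exactly
   1. Any positive affine transform of an input column leaves the output
   unchanged, which makes the axis independent of the rescaling
   constants chosen in step 2.
5. **Axis.** impulsive component = mean of the 5 UPPS residual-Z scores;
   compulsive component = mean of the 3 OCDUS residual-Z scores;
   `axis = 10 × (impulsive − compulsive)`. By construction the axis
   averages exactly 0 over the cohort it was standardized on. Five
   character bands are cut at ±10 and ±20; exact ±10 belongs to
   *balance* (the balance interval is closed) and exact ±20 to the
   moderate bands. The tie rule is overridable via `BandRule`.

Character prediction drops balance-band subjects (|axis| ≤ 10), labels
the rest by axis sign, and fits two-feature binary classifiers on
percent-of-maximum instrument totals: (PSI %, MULTICAGE %) and
(UPPS %, OCDUS %). The split is stratified 8:2 with |train| = round(0.8·n).
A tournament of six standard families (thresholded least-squares
"linear regression", logistic regression, KNN, Gaussian-process
classifier, SVM, decision tree) shares one split; prediction efficiency
is test-set accuracy in percent. The GPC uses an RBF kernel with initial
length scale 1.0, L-BFGS-B marginal-likelihood optimization, at most 100
prediction iterations and no warm start (scikit-learn's defaults). Its
probability surface is evaluated on a 0–100 × 0–100 grid and partitioned
into impulsive / uncertain / compulsive zones at p = 0.5 ∓ δ (δ = 0.1 by
default); the two zone-boundary contours are distilled into quadratic
curves OCDUS = f(UPPS) by least squares, giving a three-outcome
threshold rule whose agreement with the GPC's hard labels (abstentions
scored as disagreement) is reported.

## Statistics

- **Normality gate.** One-sample Kolmogorov–Smirnov against a normal
  with sample-estimated mean and SD, used only to prefer nonparametric
  tests. With estimated parameters the plain KS p-value is
  anti-conservative for rejecting; a Lilliefors-corrected option
  (statsmodels) is provided.
- **Mann–Whitney U.** The headline statistic is min(Uₓ, Uᵧ), equal to
  exhaustive pair counting with half-ties; z uses the tie-corrected
  normal approximation with continuity correction; Rosenthal's effect
  size is r = |z|/√(n₁+n₂), labeled small/medium/large at 0.30/0.50.
  Both one- and two-sided p-values are reported because published
  analyses of this design do not state sidedness.
- **Correlation Bayes factor.** BF10 is the two-sided
  Jeffreys–Zellner–Siow default for a correlation: the exact sampling
  density of Pearson's r (Gaussian-hypergeometric form) integrated over
  a uniform (stretched-beta, κ = 1) prior on ρ, divided by the density
  at ρ = 0, via adaptive quadrature. The 95% credible interval comes
  from the quantiles of the same gridded posterior (4001-point grid).
  Evidence labels: BF10 < 1 none, 1–10 weak-moderate, ≥ 10 strong.
  |r| numerically at 1 short-circuits to BF10 = ∞ (the integral
  diverges). The implementation is cross-checked in the test suite
  against an independent reference implementation to < 1%.
- **Band-proportion comparison.** The two impulsivity-band rows and the
  two compulsivity-band rows of the 5-band × 5-scale percent table are
  pooled into 10-value groups and compared by the U test above, with
  mean / median / (n−1) SD / IQR per group.

## The synthetic cohort generator

The generator replaces the survey data, emulating the reference cohort's
statistical shape so every downstream stage runs and is testable at desk
scale. Defaults (n = 807):

- **Demographics** drawn i.i.d. from the reference band frequencies
  (women .677; age bands .016/.159/.133/.264/.323/.105 over <18 … >60;
  education .031/.037/.147/.098/.687 over primary … university degree;
  nationality/residence continents carried as fields).
- **Latents.** Bivariate standard-normal traits I (impulsivity) and C
  (compulsivity) with correlation ρ = 0.4.
- **Subscales.** Each target (0–100 scale) is linear in one latent plus
  centered age and education codes plus Gaussian noise. Default
  intercepts/SDs reproduce the reference normalized descriptives (UPPS
  means 20.6–47.4, SDs 15.3–19.6; OCDUS means 17.3–31.1 converted from
  the raw-scale descriptives); covariate coefficients are solved from
  the reference correlation targets (all age correlations negative,
  down to −0.35 for sensation seeking and OCDUS resistance). The trait
  loading is 0.65 for all eight axis subscales — with ρ = 0.4 this
  yields an axis SD ≈ 8.6–9 and ≈ 25% of subjects outside the balance
  band, matching the reference cohort's 8.84 and 24.9%.
- **Item emission.** A subscale target is spread equally over its items,
  jittered (SD 0.6), rounded and clamped to the item range; reverse-keyed
  items and inverted subscales are emitted in observed (pre-key)
  orientation so scoring recovers the target. Rounding on coarse Likert
  ranges adds noticeable variance (≈ 11 points of SD for a 4-item 1–4
  subscale on the percent scale); this emission noise is part of the
  model-implied score covariance below.
- **MULTICAGE.** Per-item Bernoulli endorsement with logit
  −1.4 + 0.35·I + 0.9·C per scale: endorsement rises with both traits
  but more steeply with compulsivity, so flagged (≥ 50%) subjects skew
  toward the compulsive pole downstream — the structure the
  band-frequency analysis expects. The enrichment is monotone in the
  C-slope up to ≈ 0.9, beyond which flags lose selectivity.
- **Planted outliers.** A configured fraction (0 by default; the
  pipeline run config uses 0.006) of subjects is displaced by
  `outlier_shift` Mahalanobis SD units of the model-implied emitted-score
  covariance along a random direction. Directions whose displacement the
  bounded 0–100 scale would truncate below 75% of the target squared
  length are rejection-resampled (up to 20 draws), and of the two
  opposite displacements the one retaining more Mahalanobis length after
  clipping is kept. Measuring the shift in the Mahalanobis metric (not
  per-marginal SDs) is what makes an "8 SD" plant actually sit ≈ 8 SD
  from the cohort under the downstream filter, regardless of the
  cohort's correlation structure.

One named random stream per component (demographics, latents, items,
MULTICAGE, outliers) hangs off the single seed, so adding a component
never perturbs another's draws; identical config + seed reproduces the
cohort byte-for-byte.

**What the generator does not emulate:** item wording and acquiescence
effects, missing responses (the reference data were complete), real
factor cross-loadings, nationality/residence effects, and any dependence
between demographics and the latent traits beyond the linear covariate
terms. Passing tests therefore demonstrate that the pipeline's
machinery, identities and calibration behave as designed on data with
the assumed structure — not that the substantive findings generalize to
new survey samples.

## Numerical choices and degenerate inputs

- Quartiles interpolate linearly between order statistics; skewness is
  the adjusted Fisher–Pearson coefficient and kurtosis is excess
  kurtosis (conventions unnamed in the source analyses).
- Mahalanobis screening refuses constant columns (singular covariance)
  naming the offenders; residualization falls back to the remaining
  covariate when one is constant (plain Z-scoring when both are), with
  logged warnings.
- The KS gate returns a degenerate non-normal verdict (statistic 1,
  p 0) with a warning on zero-variance input instead of failing.
- axis_consistency records a per-component error for a zero-variance
  component rather than failing the other component's result.
- Tournament ties break deterministically by family name; a family that
  fails to fit is recorded and skipped, not fatal.
- With fewer than 10 labeled subjects or a single class the prediction
  stage is skipped with a warning and the rest of the report is still
  produced.

## Problem sizes

Library defaults target the reference design (n = 807; two-feature
models on ~200 labeled subjects, 161/40 split; 101×101 decision grids).
The test suite exercises the same code paths at n = 150–5000 per case
and pools rate estimates (outlier exclusion ≈ 0.1%, planted-outlier
detection ≥ 90%) over five seeds, since single draws of such rare events
are binomially noisy.

## Known limitations

- The reference study's printed model efficiencies (78.1% / 87.8% /
  80.1%) and real-data descriptives depend on the deposited survey
  database and are not recomputed here; the synthetic cohort reproduces
  their structure (e.g. UPPS/OCDUS separability, compulsive-leaning
  flagged subpopulations), typically more cleanly than real data.
- The published normalized-score table prints the OCDUS rows on the raw
  scale while its text describes 0–100 rescaling; the generator targets
  the raw-implied normalized values. The axis is invariant to this
  choice by the affine-invariance property above.
- KS with estimated parameters, age/education as equal-spaced ordinal
  codes, and the joint (rather than separate) covariate regression are
  pragmatic choices mirroring the source analyses; alternatives
  (Lilliefors, other monotone codings, separate fits) would change
  intermediate numbers but not the axis identities.
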