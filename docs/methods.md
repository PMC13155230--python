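# Methods

This note documents the statistical models implemented in `ppbc`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Cohort and data model

The unit of inference is a woman; the unit of measurement is a region of
interest (ROI) on her tumor tissue, with 1–4 ROIs per woman. Marker
expressions are analyzed on the log2 scale throughout (the log base is a
config knob; 2 is the default). Time since last birth (TSLB) enters
continuously (years) and as ordered categories. The published category
labels overlap at their endpoints ("0–3", "3–5", "6–10", "11–21"); the
binning rule adopted here is [0,3], (3,5], (5,10], (10,21] and is
configurable. When nulliparous women are included in trend or SIR analyses
they are assigned the ordinal level above the longest parous category
(score 5 with equally spaced scores 1–4 for parous categories), encoding
"longest possible time since a birth".

## Descriptive tests

Categorical characteristics are compared across molecular subtypes with
Pearson's χ² (no continuity correction); continuous ones with tie-corrected
Kruskal–Wallis. "Missing" levels are rendered in summaries but **excluded
from tests by default**: on the transcribed reference cohort this
convention reproduces the printed family-history (0.04) and TSLB-category
(0.34) p-values, while including the missing-subtype column does not.
Inclusion is a flag. Two printed rows of the reference table (breastfeeding
and age at menarche, both printed as 0.01) are not reproduced under either
convention with Pearson χ² at two-decimal rounding (both compute to
≈0.003); the source's convention for those rows is unstated, so no
agreement is forced and the transcription records the printed values as
metadata only. A Monte-Carlo p-value mode (parametric bootstrap from the
margin-product multinomial, each simulated table scored against its own
margins) is available for sparse tables and is validated against exact
enumeration.

## Confounder selection

Stage 1 regresses continuous TSLB on each candidate separately (factor
candidates tested as whole blocks); candidates with p ≤ 0.05 advance.
Stage 2 is backward elimination run in parallel on a linear model for
continuous TSLB and an **unordered multinomial logit** for the four-level
ordinal TSLB ("polytomous" is read as unordered; an ordinal logit is a
stricter model the source did not claim). The elimination criterion is the
smaller of a covariate's two p-values — i.e. a covariate is retained if
EITHER model wants it — dropping the worst covariate while that criterion
exceeds 0.05. The direction (backward), threshold (0.05), and
union-retention rule are this package's choices where the procedure was
otherwise underdetermined; an AIC mode (drop only if removal improves both
models' AIC) is available, ties are broken lexicographically, and every
drop is logged in a criterion trace. Covariates with strong prior grounds
(BMI, an established breast-cancer risk factor) can be forced and bypass
elimination. A multinomial fit failure (quasi-separation) retains the
affected covariate conservatively and is recorded.

## Per-marker models

**Screen.** OLS of each log2 marker on continuous TSLB plus the selected
confounders over all ROIs of parous women (complete cases), with the
coefficient covariance replaced by a cluster-robust sandwich clustered on
woman. The default flavor is CR1 — the Stata-style small-sample factor
G/(G−1)·(n−1)/(n−k) — with t reference on G−1 degrees of freedom; CR0 is
available. CR1 with t(G−1) mirrors the common `sandwich`/`vcovCL`
convention. A caveat documented by the validation suite: with many 1–4
member clusters and a skewed cluster-level regressor, CR1 is known to be
mildly liberal; the simulation study measures a true level of ≈0.06 at
nominal 0.05 (naive OLS: ≈0.11). CR2-type adjustments would tighten this
but are not what the mirrored convention computes.

**Mixed models.** Reproductive-factor associations use a per-woman random
intercept (exchangeable within-woman correlation), adjusted for age at
diagnosis, with Wald tests on the factor block and the intraclass
correlation σ_b²/(σ_b²+σ_e²) reported. Non-convergence falls back to OLS
with cluster-robust variance, tagged.

**Ordinal trends.** OLS on integer-scored TSLB categories with
cluster-robust variance and 95% CIs; the replication-style preset adjusts
for family history, age at diagnosis, and menopausal status, and supports
per-subtype stratification (small strata skipped with a log entry).

**Residualization.** Each marker is regressed on the confounders only
(TSLB excluded); residuals are exactly orthogonal to the design and mean
zero, and their pairwise Pearson correlations (range reported) describe the
marker dependence structure that motivates the joint analysis.

Multiplicity is controlled by Bonferroni at α/m with m = markers tested
(0.05/53 or 0.05/48 at the default panel sizes), recorded on each result.

## Sliced inverse regression

With slices given by the TSLB categories (quantile slicing available for
continuous responses), predictors are centered and whitened by the inverse
symmetric square root of the (1/n) sample covariance; the kernel
M = Σ_s p_s z̄_s z̄_s′ is eigen-decomposed and directions are mapped back
through the whitening. ROIs are treated as independent observations in the
fit. Numerical conventions: eigenvalues clipped to [0,1]; each direction
column sign-fixed so its largest-magnitude entry is positive; a ridge term
ε·I (logged, default 1e-6 when n ≤ p, off otherwise) regularizes a singular
covariance.

**Marginal dimension test.** T_d = n Σ_{j>d} λ_j ~ χ²_{(p−d)(h−1−d)} with
the classical normal-theory weights (no weighted-chi-bar refinement); the
estimated dimension is the smallest non-rejected d at α = 0.05.

**Coordinate test.** H0: marker k's row of the direction matrix restricted
to the first d components is zero. The row covariance is estimated by a
nonparametric bootstrap that resamples **women** (respecting repeated ROIs,
even though the SIR point estimate treats ROIs as independent; a naive iid
bootstrap is available for sensitivity). Each resampled direction matrix is
rotated onto the point estimate by orthogonal Procrustes before covariances
are formed — without alignment, eigenvector sign/rotation ambiguity would
inflate the covariance. Wald statistics are referred to χ²_d; a singular
bootstrap covariance falls back to a pseudo-inverse with the marker
flagged; resamples that lose all but one slice are redrawn. At least 200
resamples are required. The cited coordinate-test methodology leaves the
covariance estimator open; the bootstrap implementation is this package's
choice, so per-marker SIR p-values are not claimed to be numerically
identical to any particular analytic variant. Simulation at the default
study scale shows null rejection ≈0.05–0.06 and power ≈1.0 on a planted
single-index marker (300 women, 300 resamples).

## Synthetic-data generator

The generator emulates the structure the analysis assumes, at the reference
study's scale: 336 parous (+268 nulliparous) women; TSLB drawn by category
(targets 40.2/28.9/23.8/7.1%) uniform within bin; covariates drawn
independently with the reference cohort's marginal frequencies; ROI counts
1–4 with probabilities from the printed repeat distribution (exact counts
63/119/143/11 of 336 — the rounded percentages sum to 100.1% and would
violate the simplex constraint); marker values built from a grand mean
(8.0 log2 units), optional subtype shifts, per-year TSLB slopes (defaults
+0.06 PR, +0.04 PTEN, +0.05 fibronectin, −0.04 CD20, −0.07 CTLA4 — the
published per-year magnitudes for the markers that carried signal), k=3
per-woman latent factors whose default loadings give pairwise marker
correlations spanning roughly −0.4 to 0.9, a per-woman intercept
(SD 0.3) shared by all markers, and ROI-level noise (SD 0.5). An optional
"confounded" mode shifts TSLB by breastfeeding (−1.5 y) and parity
(+0.8 y per child beyond 2) so confounder selection has signal to find.
Default seed 20260109; all generators are deterministic given seed and
write YAML sidecars of every parameter.

What it does **not** emulate: the joint covariate distribution of the real
cohort (covariates are independent by default), missing data, image-level
counts/segmentation, subtype-specific marker profiles (unless shifts are
configured), or any spatial structure. Passing tests therefore demonstrate
that the inference machinery is correct under the assumed model — slopes
recovered unbiasedly, variance estimates calibrated, dimension and
coordinate tests behaving as designed — not that the scientific findings
would replicate on the unreleased cohort data.

## Signature scoring

Scores are plain weighted means of log2 expression over signature genes
(weights' signs encode direction), with absent genes dropped from the
denominator and an audit of the mapping returned. No internal
normalization or quantile rescaling is applied (the cited scoring
function's "default settings" are not restated in the source; the plain
weighted-mean contract is documented here instead, and integer-valued
matrices with large maxima trigger a raw-counts warning). Published
exhaustion gene lists are user-supplied files, not vendored.
Benjamini–Hochberg q-values use the exact step-up formula, validated
against the statsmodels reference.

## Problem sizes used in validation

The bundled studies run at the scale the methods target: dimension-test
calibration at n = 790 observations (p = 10, h = 4, 500 replicates) and
dimension recovery at n = 2000 (100 replicates); coordinate-test
calibration at 300 women × 2 ROIs with 300 bootstrap resamples (200
replicates); slope recovery at 336 women (200 replicates). The full
pipeline run uses the default 53/48-marker panels and ≈760 parous ROIs.

## Known limitations

* CR1 mild liberality at this cluster mix (above); interpret borderline
  screen p-values accordingly.
* The χ² reference for the dimension test uses classical weights; for
  strongly non-elliptical predictors a weighted-chi-bar reference would be
  more accurate.
* The coordinate test's bootstrap covariance assumes the retained dimension
  d is fixed; uncertainty in d̂ is not propagated.
* Stepwise selection inherits the usual caveats of data-driven confounder
  choice; the forced-covariate mechanism exists precisely to encode prior
  knowledge.
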