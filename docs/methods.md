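# Methods

## Data model and preprocessing

A cohort is one row per participant: group (OA = case, HV = control),
age (years), sex, BMI (kg/m²), measurement batch, optional
diabetes-mellitus status, and non-negative plasma concentrations (µM)
for a panel of lysoPC / PCaa / PCae metabolites. Concentration units
are treated as opaque positive reals; every analysis below is invariant
to a per-metabolite scale factor. Missing concentrations are rejected
rather than imputed — the pipeline has no imputation model and silently
filling values would change the bootstrap distributions.

Preprocessing order is batch adjustment → log(x+1) → stratification.

*Batch adjustment.* The default (`median-ratio`) rescales each batch
multiplicatively so its within-batch median matches the all-cohort
median per metabolite. A scale-based correction is robust, preserves
positivity, and on log-normal data removes an additive log-scale batch
shift exactly in the median. A `log-center` alternative (per-batch mean
centering of log(x+1), global mean restored) is provided; both collapse
a simulated between-batch variance component to <5 % of its size, and
which one the original analysis used is not recoverable — downstream
AUCs are insensitive to the choice because both are monotone within
batch.

*Transform.* Natural log(x+1). The base is irrelevant to every
AUC-based quantity (monotone transforms preserve ranks), so nothing
downstream depends on this choice; it matters only for the dispersion
distances and the Welch tests, where the natural log is the
conventional variance stabilizer.

*Strata.* Age >50 strictly (a 50-year-old is in the ≤50 stratum), BMI
≥30 inclusive (the WHO obesity threshold), sex exact; rules compose
conjunctively. Ten strata cover the designs of interest; six of them
(all, age>50, males, males>50, age>50 × BMI bands) carry signatures
into modeling.

## Dispersion homogeneity

Each participant's dispersion is its Euclidean distance, in the
log-transformed metabolite space, to its own group centroid (arithmetic
mean; a Weiszfeld spatial-median variant is available). Group
dispersions are compared by Tukey's HSD on the per-participant
distances: one-way ANOVA mean square within, Tukey–Kramer standard
errors for unequal n, studentized-range p-values. With two groups this
reduces exactly to the pooled-variance t-test, which the tests assert.
A label-permutation test of the overall F on distances exists but is
off by default — the pipeline's significance calls come from the HSD
test, and the permutation variant is provided only for users who want
the classic resampling formulation. Known property (verified by
simulation in the test suite): variance heterogeneity between age bands
is flagged far more often than OA-vs-HV differences within a band,
which is the empirical justification for age stratification.

## Bootstrap out-of-bag selection

Per metabolite and stratum of size N: B = 1000 replicates (tests and
the acceptance script use B = 200–1000; selection probabilities are
insensitive to B in this range, only the quantile noise changes). Each
replicate draws N with replacement; the OOB set is every participant
absent from the draw (expected fraction (1−1/N)^N ≈ 0.368). A
univariate logistic regression is fit on the draw and the OOB
participants are scored by its linear predictor.

Implementation note: a one-feature logistic's linear predictor is
strictly monotone in the feature, with direction equal to the sign of
the fitted slope, and the ML slope's sign equals the sign of the
training covariance Σx(y−ȳ) (the profile log-likelihood is concave with
that derivative at β=0). OOB AUC is therefore computed from the raw
feature and that sign, with no iterative fit; the test suite asserts
exact, replicate-by-replicate agreement with explicit logistic fits.

Degenerate replicates (draw or OOB set single-class) are discarded and
counted, never redrawn — redrawing would distort the resampling
distribution; an error is raised if fewer than half the replicates
survive. Empirical quantiles use linear interpolation of order
statistics (the common type-7 estimator) everywhere; selection is
threshold-sensitive, so one estimator is fixed package-wide and
cross-checked against a sort-based oracle.

Selection rule: q₀.₀₂₅ strictly greater than 0.5 (a configurable
non-strict variant exists). The reported AUC of a signature member is
its median (q50). An empty signature is a valid outcome — two of the
study strata produce none. Per-metabolite RNG streams are derived from
the master seed and the (stratum, metabolite-name) pair via CRC32, so
results are independent of panel ordering.

Measured operating characteristics at the study's sample sizes
(recomputed by the acceptance script, B=200): with 30 metabolites at
true AUC 0.70 plus 30 nulls at n=122 (72/50), ~83–87 % of true effects
are selected and ~0–1 % of nulls; on an all-null stratum of n=174 the
per-metabolite selection rate is ~0.5–1.5 % — below the nominal 2.5 %
because the bootstrap 2.5 % quantile is a conservative estimate of the
sampling lower bound.

## Classifiers

`SignatureClassifier(family, n_components, scale)` is a scikit-learn
estimator covering the three families. Features are centered and, by
default, unit-variance scaled before projection — metabolite variances
span orders of magnitude and unscaled PCA would be dominated by the
most abundant lipids; a `scale=False` switch exists because whether the
original analysis scaled is unknown. Projections:

* `pcr` — principal axes of the standardized matrix (deterministic
  sign: largest-magnitude loading positive);
* `pls` — univariate-response NIPALS (PLS1); the first weight vector is
  proportional to the feature–label covariance vector, which the tests
  verify in closed form;
* `logistic` — identity (constant columns dropped with a warning).

The projected scores feed an unpenalized maximum-likelihood logistic
regression (LBFGS, tolerance 1e-8, 200-iteration cap). On complete
separation the likelihood has no finite maximizer; the fit is flagged
(`separation_flag_`, `converged_`) and the diverged-direction scores
are returned, since AUC depends only on ranking — multivariate logistic
on a 30-metabolite signature at n≈120 separates routinely, which is
exactly the overfitting phenomenon the comparison is designed to
expose. Scoring new data always reuses the training
standardization/projection; no test-set statistic is ever consulted.

Aggregate inputs sum raw concentrations within each lipid class over
the whole panel, then apply log(x+1) — the same order as individual
metabolites (sum-then-log on raw µM keeps the aggregate interpretable
as a total class concentration).

## Model bootstrap and consistency comparison

The model bootstrap mirrors the selection bootstrap: per replicate,
refit the classifier on the draw, record training AUC on the draw and
test AUC on the OOB set, discard-and-count degenerate replicates.
Metabolite selection is *not* re-run inside replicates: selection has
its own bootstrap beforehand and the model bootstrap conditions on the
chosen feature set. The optimism this induces is inherent to the
sequential design being modeled and is shared by all families equally,
so the *comparison* between families is unaffected. Single-score fits
(k=1 PCR/PLS, one-feature logistic) use the monotonicity shortcut
described above, verified against full fits.

The consistency grid reports train/test quantiles at 2.5/50/97.5 %,
differences (train − test), the mean absolute difference across strata
per quantile, and overall (all 18 quantile × stratum cells per family).
Component selection minimizes |mean train − mean test| with ties toward
smaller k; on one-dominant-direction data k=1 is recovered, and on
noise the gap grows with k so the tie-break also lands on 1.

Known behavior on pure noise (p=30, n=120, measured in the acceptance
suite): multivariate logistic reaches median training AUC ≥ 0.9 with
median OOB AUC ≈ 0.5 — a gap of ~0.4 — while one-component PCR's
median gap is ~0.05. Part of that residual PCR gap is irreducible at
this n: the bootstrap draw holds only ≈0.632·N distinct participants,
so even a pure-noise fitted score has expected training AUC ≈ 0.5 +
E|Z|·σ_AUC(0.632·N) ≈ 0.55 at N=120. The gap falls below 0.04 by
N=200.

ROC bands use vertical averaging: each replicate's OOB ROC is
interpolated on a fixed FPR grid and the mean with 2.5/97.5 % envelopes
is exported. At FPR=0 the step-function average carries a positive bias
of order 1/(n_controls+1); band consumers should read the interior of
the curve.

## Demographic statistics and sensitivity analyses

Sex-ratio comparisons use the 2×2 chi-square with Yates continuity
correction — chosen because it reproduces the published p-values from
the published counts exactly (the uncorrected statistic does not), and
because it tracks the doubled one-sided margin-conditioned exact tail
to <0.002 on all six mixed-sex strata. Continuous comparisons use
Welch's unequal-variance t-test (from raw values or from summary
moments with Satterthwaite df); checks against printed p-values are
bound-level only since printed moments are rounded.

The diabetes-mellitus sensitivity utility Welch-tests each signature
metabolite's transformed levels between DM and non-DM participants
within OA and HV separately (unadjusted p < 0.05; no multiplicity
correction, matching the descriptive character of the check), flags
members significant in either group, and returns the reduced signature
for a model re-run. Note the union rule's null flag rate is ≈ 2α−α²,
not α; the per-test rate is calibrated at α.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not the
measurement process:

* **Demographics.** Sixteen (group × sex × age-band × BMI-band) cells
  whose counts are fully determined by the published stratum marginals
  (346 total; 152/194 case/control; 250 over 50; 122 older males; …)
  and reproduced exactly. Age and BMI are truncated normals honoring
  each band; the location parameter is solved numerically so the
  *truncated* mean equals the published group mean. Means for the
  unpublished age≤50 cells are derived by moment subtraction from the
  whole-cohort and age>50 rows; their SDs are round plausible values.
  Conditional on group and band, age/BMI are sex-independent — real
  cohorts are not, but no sex-specific moments beyond the printed rows
  exist to calibrate more.
* **Concentrations.** Log-normal: log-concentration = base mean (4.0)
  + 0.4 × a standard MVN with exchangeable correlation ρ=0.5 within
  each lipid class and 0 across classes, + an additive per-(batch,
  metabolite) shift N(0, batch_sd), + for cases a shift of
  d = √2·Φ⁻¹(target AUC) standard deviations, optionally scaled by a
  per-cell multiplier to concentrate signal in a subgroup (e.g. older
  males). Because log(x+1) is monotone, the marginal univariate AUC
  equals Φ(d/√2) exactly regardless of ρ, which the tests verify by
  Monte Carlo to ±0.01. Base scale parameters are arbitrary (no
  per-metabolite concentration scales are published) and the analysis
  is invariant to them.
* **Not modeled.** Measurement error, limits of detection, missingness,
  non-normal tails, inter-class correlation, age- or BMI-dependent
  metabolite trends. Passing tests therefore demonstrate that the
  *machinery* behaves as specified under the design's assumptions, not
  that the published signatures would replicate in new clinical data.

## Problem sizes and numerical choices

Tests and the acceptance script run with B=200–1000 bootstrap
replicates, 10–20 generator seeds per property, and 200–500 simulation
replicates for calibration checks — sizes at which the asserted
properties are stable while the full suite completes in a few minutes.
Quantiles are type-7 throughout; the truncated-normal location solver
uses Brent's method to 1e-8; PCA sign is fixed by the
largest-magnitude loading; near-constant columns (sd ≤ 1e-10 relative)
are treated as constant. Degenerate inputs raise typed errors
(single-class labels, rank-deficient component requests, all-zero
batches, groups of size one) rather than propagating NaNs.
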