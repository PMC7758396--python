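# Methods

## The classification model

The stratifier is two-class quadratic discriminant analysis (QDA) on the
panel's normalized expression vector. QDA is used because the target
decision statistic — a difference of two class-specific polynomials with
constant, per-gene linear, and per-gene-pair quadratic terms — is exactly
the form of a Gaussian class-conditional log-likelihood ratio with
class-specific covariances; it is the unique standard estimator whose
decision function has that shape. The fitted object stores both
parameterizations: the Gaussian one (class means, covariances, priors)
and the expanded polynomial coefficients. Their equality,

    const_k + linear_k' x + x' quad_k x
        = log pi_k - 1/2 log|Sigma_k| - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k),

is asserted on random probe vectors at every fit in the test suite (the
constant -p/2 log 2 pi is omitted on both sides; it cancels in the score
difference). Ties at D = 0 are assigned to the negative (lower-risk /
benign) class.

Assumptions: within-class multivariate Gaussian CtS values, independent
patients, and a fixed, known panel. Nothing in the fit uses PSA, Gleason
score or any covariate; those enter only as comparison classifiers or
subgroup filters.

### Parameters

* `priors` — "proportional" (default) uses training class frequencies;
  appropriate for the imbalanced clinical cohorts this mirrors and it
  reproduces their high-sensitivity/low-NPV operating character.
  "equal" is available for prevalence-free scoring. The original study
  does not state its choice.
* `shrinkage` (default 0.1) — blends each class covariance towards the
  diagonal of the pooled covariance, `(1-s) S_k + s diag(S_pooled)`.
  With 14 genes and as few as ~50 samples in the minority class, raw
  class covariances are ill-conditioned; 0.1 is a mild, dimensionless
  stabilizer. `shrinkage=0` recovers textbook QDA and raises a clear
  error when a covariance is singular.
* `positive_class` — which label gets the plus sign in D; swapping it
  negates every D score (tested property).

Because the discriminant is refitted to whatever feature scale it is
given, all calls are invariant to a common affine rescaling of the
features — in particular to reporting CtS as a bare ratio or x1000.
Both scales are supported everywhere; the x1000 convention is used for
reported tables.

### Evaluation protocols

Resubstitution (default) scores the training cohort itself — this is how
the original analyses report performance, and it is optimistically
biased for a ~240-parameter model. Stratified k-fold (seeded, k >= 2) is
provided for out-of-sample estimates and is used for the null-control
check (below), where resubstitution optimism alone would lift AUC to
~0.60 and mask the absence of signal.

## Normalization

Replicate Ct readings are averaged arithmetically per (patient, gene);
each panel gene's mean Ct is divided by the patient's beta-actin mean
Ct. No replicate outlier rejection is applied (no QC rule is defined for
the assay); replicate ranges above one cycle are logged. No PCR
efficiency correction, delta-delta-Ct, or standard curves — the ratio
itself is the assay's expression value.

## The synthetic cohort generator

The generator emulates the two-group study structure the analysis
assumes, on the x1000 CtS scale: group B (lower-risk) gene means
`mu_b`, group A means `mu_b + delta`, a common within-group covariance
with per-gene SDs `sigma` and a single exchangeable gene-gene
correlation (default 0). Below the expression level it inverts the
normalization: a per-patient actin Ct ~ N(25, 1.5^2) cycles, gene
true Ct = (CtS/1000) x actin Ct (multiplicative, because CtS is a
ratio), and additive N(0, 0.15^2) technical noise per PCR replicate
(3 replicates), for the panel genes and the actin channel alike.

Calibrated defaults (stratification task, 149 vs 53 patients):

* `delta` — the nine reported group differences: CST3 +1008, VEGFA
  +953, GOLM1 +813, CCND1 +727, LMTK2 +552, PMP22 +534, TMPRSS2 +523,
  PIP5K1A -274, PTEN -121. The five remaining genes (CDK1, EZH2, PCA3,
  ANXA3, GSTP1) shift by |60| — large but deliberately borderline; the
  signs (ANXA3, GSTP1 negative) are an arbitrary documented choice.
* `sigma` — 120 for the nine shifted genes (~11% CV at mid-scale); for
  the five borderline genes, 60/(1.96 sqrt(1/149 + 1/53)) ≈ 191.4, the
  SD at which a two-sample t-test of a |60| shift at the default group
  sizes is non-significant roughly half the time.
* `mu_b` — centred per gene as `1100 - delta/2`, so both group means
  sit mid-range of the CtS band implied by a 25-cycle actin reference
  and a 40-cycle PCR. For CST3 the +1008 shift is wider than that band
  allows exactly, so its implied group-mean Ct values span ~14.9-40.1
  cycles — accepted as a 0.1-cycle transgression of the nominal 15-40
  reading range.
* Diagnosis task: 202 cancer vs 191 benign with `delta` at half the
  stratification values — no published effect sizes exist for the
  benign contrast, so these defaults are arbitrary and only fix a
  consistent simulation target.

What the generator does **not** emulate, and what passing tests
therefore do not show about real data: skewed or heavy-tailed CtS
distributions (real urinary qPCR is strongly right-skewed; the
Gaussian family here is the minimal choice consistent with t-test-based
analysis), PCR efficiency and preamplification bias, urine cellularity
and RNA-yield variation, missing wells, and batch effects. One
consequence is deliberate: keeping the Gaussian mass strictly positive
bounds the usable `sigma` well below the value that would reproduce the
published per-gene p-values at the study's n, so the simulated
default cohort separates almost perfectly (resubstitution AUC ≈ 1.0)
rather than at the published AUC ≈ 0.9. The published p-values and the
published mean differences are mutually consistent only under noise
levels wider than the physical CtS range, which a positive-support
Gaussian generator cannot represent; the defaults favour the mean
differences, which are the quantities the calibration-recovery checks
assert.

## Evaluation statistics

* **Wald intervals**: `100 (p ± 1.96 sqrt(p(1-p)/n))`, never clipped to
  [0, 100]. This is the interval form the published tables use (their
  >100% upper bounds identify it), and it reproduces every
  count-derivable CI cell of the urine-cohort tables to two decimals.
  The tissue-cohort table's printed CIs are not derivable from its own
  counts and are treated as misprints (its point estimates reproduce).
  Wilson or Clopper-Pearson alternatives would break table
  reproduction and are intentionally not offered as defaults.
* **ROC/AUC**: threshold sweep over unique scores, higher score = more
  positive; trapezoidal area, equal to the Mann-Whitney concordance
  with half-credit ties (asserted as a property test to 1e-12). AUC CI
  by the Hanley-McNeil standard error, clipped to [0, 1]. No DeLong CI,
  partial AUC, or decision-curve analysis.
* **Differential expression**: per-gene two-sample t-tests, Welch by
  default (the pooled variant is a parameter), reported on the x1000
  CtS scale. No multiple-testing correction is applied, matching the
  source analysis style.
* Rendering: percentages rounded half-up to 2 decimals at print time
  only; the "point (upper-lower)%" order follows the published tables.

## Risk-label derivation

`derive_risk_label` binarizes clinical criteria: Gleason total > 7, or
Gleason 4+3, or stage >= T3, or PSA > 20 ng/ml (strictly), or more than
half of biopsy cores with cancer => higher risk; otherwise lower risk.
Missing fields are non-qualifying (logged); all-absent is an error. The
Gleason-6-and-7 and Gleason-7-only subgroup analyses are implemented as
row selections over the same pipeline, not separate methods. Note the
source cohort description is internally inconsistent about the
higher/lower split (142/60 in one passage, 149/53 in the tables); the
149/53 split underlying every printed metric is used as the default
cohort size.

## Numerical choices

* Covariances use ddof=1; precision matrices come from a Cholesky
  factorization (error advising shrinkage when it fails); log
  determinants via `slogdet`.
* Exchangeable correlation is admissible only in (-1/(p-1), 1); the
  config validator names the offending value otherwise.
* Simulated CtS must be strictly positive and implied raw Ct values
  strictly positive; violations raise rather than truncate, so a
  pathological configuration cannot silently skew the distribution.
* Seeds: every stochastic component takes an integer seed; profile
  noise and replicate noise use independent child streams of it, so
  the expression-level cohort is unchanged when only replicate-level
  settings vary.

## Problem sizes in the checks

Calibration recovery uses 10,000 patients per group (3 Monte-Carlo SEs
≈ ±5 on the x1000 scale for sigma=120); the null control uses 2,000 per
group with 5-fold cross-validation; oracle-agreement and property
checks run on study-sized cohorts (~200-300 patients). The full suite
and the acceptance script each complete in well under a minute on one
CPU.

## Known limitations

* Resubstitution reporting is optimistic; it is the default only
  because it mirrors the reporting convention of the analyses this
  package reproduces. Use the kfold protocol for honest estimates.
* The original study's fitted coefficients were never published, so no
  attempt is made to reproduce them — only the functional form, the
  fitting procedure, and the printed count-derivable metrics.
* The direction-of-expression semantics of CtS are left to the caller:
  a larger Ct ordinarily means less transcript, yet increased CtS is
  conventionally described as upregulation in this assay family; the
  package simulates and classifies CtS values directly and takes no
  position.
* PSA-as-classifier baselines require a dichotomization threshold that
  the source tables never state; it is a configuration knob with no
  default.
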