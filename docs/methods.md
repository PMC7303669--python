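# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that affect results.

## Synthetic cohorts

The generator draws two cohorts sharing one set of feature-level
parameters, so a model trained on one is meaningful on the other. Feature
*j* of subject *i* is

```
x_ij = b_j + s_j (age_i − 68) + γ_{site(i),j} + δ_{site(i),j} (μ_{g(j),label(i)} a_j + ε_ij)
```

with baseline `b_j ~ N(0,1)`, age slope `s_j ~ N(0, age_slope_sd²)`
(default 0.02 per year — a modest trend over the ±9-year age SD of the
cohorts), an affected-feature indicator `a_j` (Bernoulli,
`affected_fraction` = 0.3), additive site effects
`γ ~ N(0, site_additive_sd²)` and multiplicative ones
`δ = exp(N(0, site_multiplicative_sd²))` drawn per site and feature, and
residual noise `ε` with unit SD and exchangeable within-group correlation
(`within_group_rho` = 0.2 — the real data's feature covariance is
unreported, so this is an explicit assumption, not an estimate).

Defaults are the study conditions: cohort sizes 173 HC + 76 AD (one
training site) and 67 SMC + 61 MCI + 61 AD spread over four clinic sites;
disease shifts graded μ(SMC) = 0.4, μ(MCI) = 1.2, μ(AD) = 2.0 SD on
affected features (the severity ordering is documented as illustrative —
only its monotonicity, not its magnitudes, is taken from the reported
score patterns); site-effect magnitudes graded by modality — additive SD
2.0 / 0.5 / 0.0 and multiplicative log-SD 0.4 / 0.15 / 0.0 for diffusion /
anatomical / rs-fMRI — mirroring the reported large / moderate / invisible
site differences. Demographics are truncated normal draws matching the
published per-group means and SDs. The multiplicative effect scales the
residual (noise plus disease deviation), not the covariate-predicted part,
which is exactly the batch model the harmonization step assumes — so
harmonization is well-posed on these data by construction.

The voxel-wise low-frequency power map of a real brain has ~1.4 × 10⁵
voxels; the generator defaults to 500 synthetic voxels (override
available) because every pipeline stage is dimension-generic and the
smaller default keeps the full study runnable in minutes.

What the generator does **not** emulate: registration error, head motion,
spatial autocorrelation beyond the exchangeable within-group term,
non-linear age effects, label noise, and missing data. Passing tests
demonstrate correctness of the statistical machinery under its stated
model, not performance on real MRI.

## Signal-level rs-fMRI features

*Sparse partial correlations.* Component time courses are standardized;
the penalized precision is estimated by the graphical lasso on the
correlation matrix, so the penalty is per off-diagonal entry on the
correlation scale. The penalty of the original analysis was expressed in a
different software's scaling; no numerical equivalence between that value
and this module's penalty is claimed — the penalty is a free parameter
here. Partial correlations are `−Θ_ij/√(Θ_ii Θ_jj)`, clipped to [−1, 1];
the upper triangle is vectorized in fixed row-major (i < j) order.

*ALFF.* Power in (0, 0.1] Hz from a one-sided periodogram after linear
detrending, normalized by the mean across voxels (so normalized values
average exactly 1). A plain periodogram, not Welch averaging, because
realistic acquisitions (110–200 volumes) leave no room for segment
averaging. The DC bin is never included. Linear detrending of a pure
sinusoid leaks a small (≲0.5%) fraction of its power across the spectrum;
tests account for that. Whether "low-frequency amplitude" means power or
its square root differs between conventions; the default is power, with
`amplitude=True` available.

## Age correction

Ordinary least squares of each feature on age, fitted on training-cohort
healthy controls only (disease-free aging), then subtracted from every
subject of both cohorts using the same slopes — the clinic cohort is
corrected with training-derived slopes, which couples the cohorts in
exactly one direction (training → clinic). Age correction runs before
ComBat by default; the order is a config switch
(`harmonization_order`) because the two operations do not exactly commute.

## ComBat

The standard parametric empirical-Bayes formulation: per feature, a linear
model with site indicators plus protected covariates (age, sex linear /
indicator, years of education, clinical label as category indicators, MMSE
linear); standardization by the site-size-weighted grand mean and pooled
residual variance; per-site location (`γ`) and scale (`δ`) estimates shrunk
by a normal prior on `γ` and an inverse-gamma prior on `δ` with
moment-matched hyperparameters, solved by iterative conditional updates
(absolute tolerance 1e-6, max 100 iterations). With
`empirical_bayes=False` the apply step exactly equalizes per-site means
and variances. Harmonization happens within the clinic cohort only; the
training and clinic cohorts are never harmonized against each other
because their clinical composition differs — site and diagnosis would be
confounded.

The implementation is validated against Bioconductor sva's `ComBat` (same
data, same covariates) to ~1e-5; the residual difference is sva's looser
default convergence tolerance. Known property: under strong scale
heterogeneity (multiplicative effects of typical factor ≳1.5), EB
shrinkage of `δ` deliberately under-corrects extreme features, so repeated
harmonization is only approximately idempotent in moderate-effect regimes.

## Penalized logistic models

Both solvers minimize the **mean** negative log-likelihood plus penalty, so
λ is comparable across training sets of different size (fold-to-fold and
training-to-refit); the intercept is never penalized; features are
standardized using statistics of the fitting rows only (refit inside every
CV fold — anything else leaks test information); zero-variance columns are
dropped and recorded.

*Elastic net* (single feature groups): cyclic coordinate descent on the
iteratively reweighted least-squares surrogate, fixed feature order,
coefficient tolerance 1e-7, with a step-halving safeguard that makes the
penalized objective provably non-increasing. The inner loop is
JIT-compiled (numba) so the 2415-feature connectivity model fits in
milliseconds.

*Group lasso* (combined models): proximal gradient with block
soft-thresholding, backtracking line search (step halved until the
majorization holds, grown 1.25× after success), group weights `√|g|` (the
standard size normalization), exact zero blocks by construction.

Hyperparameter grids: α ∈ {0.1, …, 1.0} and λ log-spaced over 4 decades
down from the smallest fully-sparsifying value (computed from the data);
these are documented choices, not reproductions — the original grids are
unreported. Ties in CV AUC resolve toward larger λ (the sparser model).
The 173:76 class imbalance is left unweighted; AUC is invariant to class
prevalence, which is the evaluation target.

## Evaluation

AUC is the Mann–Whitney estimate `(concordant + 0.5·tied)/(n₁n₀)` via the
rank-sum formula. Nested CV: stratified 10-fold outer and inner loops,
10 repeats (defaults); the inner loop picks the grid point with the best
pooled inner-fold AUC, the outer training set refits it, outer-fold scores
are pooled per repeat into one AUC, repeats are averaged. Stratification is
the default because the minority class would otherwise occasionally vanish
from a fold; non-stratified splitting falls back with a warning when that
happens. The final transferred models are tuned by a single 10-fold CV on
the whole training cohort and refit on all training rows.

maxT permutation: labels are permuted independently within each
comparison's subject set (the comparisons span different cohorts and
disjoint subject subsets, so a joint relabeling is not well-defined across
them); per permutation only the maximum AUC over the family is kept;
p = (1 + #{max ≥ observed})/(B + 1), one-sided (high AUC is the signal),
minimum attainable 1/(B+1). Because score ranks are fixed under label
permutation, each permutation is a single inner product — B = 10,000 over
52 comparisons takes seconds. For training-cohort comparisons the
permutation test permutes labels against the fixed cross-validated scores
(recomputing a full nested CV inside each of 10,000 permutations is not
computationally faithful at this scale); both the fixed-score and refit
modes exist at the function level, fixed-score is the pipeline default.

In the full study the training-cohort score set is the pooled out-of-fold
prediction from the tuning CV at the selected hyperparameters; repeated
nested CV is available (`StudyConfig.nested_cv=True`) when an
optimism-free training AUC is the quantity of interest.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full default cohort
sizes but scale the evaluation machinery: α ∈ {0.5, 1.0} with 6 λ values
and 5 tuning folds; nested CV with 5 × 5 folds and 2 repeats; 2000
permutations for the study run, B = 500 × 200 replicates for the
family-wise-error simulation. These sizes are the package's choices for a
fast, deterministic demonstration; all of them are configuration values,
and the defaults in `StudyConfig`/`CvSpec` remain the full-size settings.

## Degenerate inputs and tie rules

Scores exactly at the 0.5 cutoff classify as the more-severe class. An
empty predicted class leaves PPV/NPV as NaN with a warning. Constant time
series have zero band power; a fully constant voxel set has no defined
ALFF normalization and errors. A non-positive-definite generated precision
matrix is diagonally loaded (logged). Unseen site codes at ComBat apply
time are an error — no extrapolation. Single-site ComBat degenerates to a
near-identity and warns.

## Known limitations

- No multinomial (three-class) models; the design is binary HC-vs-AD
  scoring transferred to finer-grained groups.
- No confidence intervals on AUC and no paired AUC tests.
- The synthetic generator's effect sizes are illustrative; absolute AUC
  levels on synthetic data say nothing about real-data performance, only
  the qualitative transfer behaviour does.
- ComBat assumes each site's effects are exchangeable draws per feature;
  structured (e.g. region-correlated) scanner effects violate this and are
  not simulated.
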