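# Methods

## The estimation problem

A national rate of a binary child outcome (death before age five, in the
motivating application) is to be predicted from a two-stage stratified
cluster survey.  Clusters (census enumeration areas) are sampled within
urban/rural strata, then children within clusters; each sampled child
carries the design weight `w_ic = N_c / n_c`, where `N_c` is the cluster's
population count of eligible children and `n_c` its realized sample count.
`N_c` is allowed to be fractional because in practice it comes from
dividing a census total by a cluster count (e.g. 2,552,406 / 18,772 =
135.969).  The pipeline compares four ways of turning such a sample into a
national rate: logistic model fitted with or without the weights, crossed
with a prediction step that does or does not weight the cluster-specific
rates, each judged by its bias against a known reference rate.

## Synthetic population and sampling design

The generator builds a finite census frame: `K_pop` equally sized clusters
of `N_c` children each, a fraction `urban_fraction` of clusters urban.
Child outcomes follow a logistic model

    logit P(y=1 | x, c) = β₀ + βᵀx + u_c,     u_c ~ N(0, σ_u²),

with categorical covariates (level probabilities optionally
stratum-specific) and a cluster-level random intercept `u_c` capturing
unobserved cluster heterogeneity.  The frame carries each child's true
probability and realized outcome; `population_rate` is the frame's outcome
mean and serves as the reference π for synthetic bias calculations.

Sampling is two-stage.  Stage one draws `sampled_clusters` clusters by
simple random sampling without replacement within strata, allocated
proportionally to stratum cluster counts (largest-remainder rounding), so
cluster inclusion is equal-probability.  Stage two draws children without
replacement within each selected cluster with target per-stratum counts;
the realized count is

    n_c = round(N_c · expit(logit(n_target_h / N_c) + φ · u_c)),

clipped to [1, N_c].  The informativeness parameter φ ties a child's
inclusion odds to the cluster's outcome risk.  Two properties follow by
construction: the emitted weight `N_c/n_c` is exactly the inverse
stage-two inclusion probability (so the weighted sample mean is
design-consistent at any φ), and at φ = 0 the realized `n_c` equals the
configured target exactly, reproducing a classical self-weighting-within-
stratum design.  Placing informativeness at the child-inclusion stage
rather than at cluster selection is a deliberate design choice: with
equally sized clusters and a weight defined as `N_c/n_c`, informative
*cluster* selection would leave all weights identical and no weighting
scheme could respond to it; informative *child* inclusion makes the
standard weight itself the correcting instrument, which is the phenomenon
the package exists to exhibit.

Defaults (chosen to emulate the motivating survey at desk scale): 500
clusters × 120 children (60,000 children; the real frames hold ~2.4–2.6
million in 12,6–18,8 thousand clusters — the scale-down keeps hundreds of
replicates cheap while leaving cluster counts large enough for jackknife
and design-effect asymptotics), 15% urban clusters, σ_u = 0.5,
β = (−2.50, −0.29 for female sex, +0.25 for rural residence) giving a
population rate ≈ 0.09 (the 2004-survey level), 100 sampled clusters, and
per-cluster child samples of 12 (urban) / 22 (rural) — urban clusters
yield fewer eligible children per cluster, so design weights vary by
stratum exactly as in the real survey, which is what makes the weighting
comparisons non-degenerate.  One integer seed drives three derived
substreams (population, stage one, stage two), so samples can be redrawn
from a fixed frame independently.

What the generator does *not* emulate: household nesting (children are
drawn directly within clusters), unequal cluster population sizes,
non-response and frame under-coverage, and continuous covariates.  Tests
passing on this synthetic world certify the estimators' design properties
— unbiasedness, variance calibration, the corrective effect of weights —
not the substantive epidemiology of any real survey.

## Model fitting

All three weighting modes maximize
`Σᵢ ωᵢ [yᵢ log πᵢ + (1−yᵢ) log(1−πᵢ)]` by iteratively reweighted least
squares: ωᵢ = 1 for the unweighted mode, ωᵢ = w_ic for pseudo-likelihood.
The third mode (`eq7_literal`) instead scales the linear predictor,
`logit(πᵢ) = (βᵀxᵢ)·w_ic` with ωᵢ = 1; the intercept column is left
unscaled — the only reading that keeps the model identified ("w₀₀ = 1").
This form is implemented for fidelity to the predictor-scaled
parameterization some applied analyses print, and is documented as not
design-consistent; the pseudo-likelihood mode is the survey-weighted
estimator proper.  Numerical choices: dummy coding with the
first-declared level as reference; β initialized at 0; step-halving on
any deviance increase; convergence when the deviance change falls below
1e-8, capped at 100 iterations; fitted probabilities clipped to
(1e-10, 1−1e-10); a singular information matrix raises an error naming
the collinear columns; |β̂| > 15 flags suspected separation.  The
model-based covariance is the inverse observed information at β̂.
Records with a missing modelled covariate are excluded by the caller
(the descriptives module's screen drops *variables* with ≥ 1/3 missing,
the rule applied to the motivating data).

Survey-robust covariance uses the stratified delete-one-cluster
jackknife: within each stratum h (K_h clusters), each cluster is deleted
in turn, the remaining likelihood weights in that stratum rescaled by
K_h/(K_h−1), and

    V = Σ_h (K_h−1)/K_h · Σ_c (β̂_(hc) − β̂)(β̂_(hc) − β̂)ᵀ.

Replicate fits warm-start at β̂.  Wald p-values use a normal reference
for model-based SEs and a t reference with `clusters − strata` degrees
of freedom when the jackknife covariance is attached — standard survey
practice where the source analysis is silent.  Whether the original
jackknife was stratified is not stated there; stratifying by urban/rural
is this package's choice.  AIC = 2p − 2·loglik is reported for the
unweighted mode only; a weight-scaled pseudo-likelihood is not a
likelihood, so information criteria are withheld for weighted fits
(matching the behaviour of the survey software the source analysis
used).  AIC comparison is reported, with selection left to the caller.

## Prediction and bias

The unweighted national rate is `π̂ = Σ π̂_ic / n` with variance
`π̂(1−π̂)/n`.  The cluster-weighted rate averages cluster-specific rates
`π̂_c` (means of fitted probabilities within cluster) with terms
`n_c/m̄`, `m̄ = Σn_c/K`, and variance
`(1/K) Σ_c (π̂_c − π̂*)²/(K−1) · (n_c/m̄)²`.  As printed, the
cluster-weighted point estimate is algebraically identical to the
unweighted mean (`Σ_c π̂_c n_c/(K m̄) = Σ π̂_ic/n`); the implementation
preserves this identity (property-tested to machine precision) and
surfaces it in formatted output rather than hiding it.  Because of the
identity, the package additionally provides an opt-in
*population-weighted* variant `π̂_pop = Σ_c π̂_c N_c / Σ_c N_c`, which
weights each cluster by the population it represents instead of its
realized sample share — the interpretation under which "considering
cluster weights" actually changes the estimate.  It is never the
default, and its variance reuses the squared-term form with
`N_c/mean(N_c)`.  Bias is `estimate − reference`; references given per
1,000 live births are converted to proportions at the boundary.  The
finite population correction `sqrt((N−n)/(N−1))` is computed and
reported but not applied to any variance by default (it is ≈ 0.996–0.998
at national scale); `apply_fpc` multiplies an estimate's SE by it on
request.

## The experiment grid

`run_bias_grid` subsamples whole clusters within strata at each
configured fraction (default 1.0/0.75/0.50/0.25, one draw per fraction,
independent across fractions), fits the model unweighted and
pseudo-likelihood-weighted, and computes both (optionally all three)
prediction estimators from each fit — four (six) rows per fraction.
Subsampling is without replacement, matching the stated intent of
re-analysing reduced samples; a with-replacement flag reproduces a
cluster bootstrap, relabelling repeated clusters as distinct primary
sampling units.  A non-converged fit fails only its own cells.

## Validation scenarios and their sizes

The acceptance suite runs, at one CPU, in about a minute: jackknife
calibration uses K = 50 clusters and 200 redraws from one fixed frame
(the mean jackknife SE over the Monte-Carlo SD of the sex coefficient
falls within [0.8, 1.25]); parameter recovery uses 200 independent
surveys of n = 5,000 with σ_u = 0 and a non-informative design, with
*balanced* strata — under the 15% urban default the urban-baseline cell
holds only ~28 events and the known O(1/cell) small-sample bias of the
logistic MLE intercept becomes resolvable at 200 replicates, which is a
property of the MLE, not a failure of recovery, so the scenario is
placed in the regime the check is about; the informative-design study
uses φ = 1, σ_u = 0.7 and 100 replicates, comparing intercepts on a
marginal (sex-only) model — whose intercept is the population baseline,
shared by both fits, rather than the sparse urban-cell baseline — and
comparing the design-weighted pipeline (weighted model +
population-weighted prediction) against the design-ignorant one
(unweighted model + unweighted prediction), the two corner cells of the
experiment grid.

## Known limitations

Only the single-component weight `N_c/n_c` is modelled (no
post-stratification, non-response, or household-level factors).
Variance estimation for the predicted rate is exactly the printed pair
of formulas — no linearized or replication variance for π̂*.  The
eq7_literal mode is provided for comparison, not use.  Multi-category
outcomes, DHS recode-file parsing, and missing-data imputation are out
of scope.
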