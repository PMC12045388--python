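# Methods

## Problem and estimands

A cohort of disability beneficiaries is observed with a binary treatment
A (participation in an employment-support program), a binary outcome Y
(any benefits forgone because of work during follow-up), subgroup labels
(program: SSI / SSDI / Concurrent; RFC-assessment availability:
physical-only / mental-only / both), and categorical or ordinal
covariates describing personal, health/functional, and environmental
characteristics. Treatment is not randomized; covariates influence both
A and Y. Two estimands are reported: the ATT (effect among the treated,
natural for a matched analysis) and the ATE (population average, natural
for the model-based analysis), each on the risk-difference and
odds-ratio scales.

## Synthetic-cohort generator

The generative model is a pair of logistic regressions sharing
covariates; subgroup (program × RFC) membership shifts both intercepts.
The true conditional treatment effect is a single log odds ratio ψ* on
the outcome scale. Per-record ground truth (e(x), p1(x), p0(x)) and
Monte-Carlo oracles for the marginal ATT/ATE are exposed.

Defaults emulate the published marginal structure of the target
population: sex 52.71% male, education three levels, a six-category
diagnosis mixture, six BMI classes, four census regions, work stoppage
due to health 69.46%, pain symptoms 91.85%, program mixture
0.249/0.504/0.247, RFC mixture 0.4712/0.4278/0.1010, and treatment and
outcome prevalences 5.12% and 11.20%. Intercepts are calibrated to hit
those prevalences by Monte-Carlo bisection (200,000 draws, fixed
internal seed) at scenario construction, so the calibration is
deterministic and independent of any analysis. Roughly a half-dozen
covariates carry nonzero coefficients in *both* models (log odds within
[−0.7, 0.7]), strong enough that crude and adjusted estimates visibly
differ. RFC-domain covariates are structurally missing when the
corresponding assessment is absent, and three of four mental-function
domains carry additional completely-at-random missingness (0.27–0.30),
matching the ">25% missing" regime of the emulated data.

Randomness uses four independent streams (covariates, treatment,
outcome, missingness) spawned from the scenario seed, so changing the
missingness configuration does not perturb treatment or outcome draws.
Missingness is applied after outcome generation and is therefore
non-informative; treatment and outcome are never missing.

What the generator does **not** emulate: the real joint covariate
dependence (only marginals are matched), free-text fields, longitudinal
benefit ledgers, and informative missingness. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to real-data pathologies outside them.

Misspecification switches describe the *analyst's* model, not nature:
`omit_confounder_from_{propensity,outcome}` marks a named confounder to
be dropped from one model block at analysis time (the generator always
simulates from the full truth), while `nonlinear_truth` adds an
interaction of the first two covariates (coefficient 0.8) to both true
linear predictors.

## Preprocessing

Categorical covariates expand to k−1 indicators with the
lexicographically first observed level as reference (the choice is
arbitrary; determinism matters more). Any missingness becomes a
per-covariate missing-indicator column and missing entries contribute 0
to the value columns, so no record is ever dropped. Zero-variance
columns are removed with a logged warning. The frequentist arm builds
six overlapping strata (program × RFC availability, with
both-assessment records appearing in both RFC strata of their program);
the Bayesian arm uses one pooled design in which every record appears
exactly once — the row-count identity
Σ strata = n + #(both) is tested explicitly.

## Frequentist arm

Propensity scores come from a maximum-likelihood logistic fit (IRLS via
the binomial GLM, tolerance 1e-8, ≤100 iterations; standard errors from
the inverse observed information, which equals the expected information
under the canonical link). Perfect separation (detected during IRLS) or
non-finite standard errors raise a named error suggesting penalization;
merely large, imprecise coefficients on sparse cells are kept, as
standard software keeps them. Collinear columns are dropped by pivoted
QR.

Matching is greedy 1:1 nearest-neighbor without replacement on the
logit of the propensity score: treated units in descending logit order,
each claiming the unused control with the smallest absolute logit
difference; a treated unit whose nearest control exceeds the caliper is
excluded. Ties are broken by the smallest control record_id, making the
pairing fully deterministic; an equal-logit run is scanned to its
smallest-id active member. The caliper is an absolute width on the
logit scale by default (0.01); `caliper_units="sd"` switches to the
common alternative of caliper × SD(logit). Synthetic-cohort analyses in
the tests and the acceptance script use 0.1 on the logit scale because
their cohorts are two to three orders of magnitude smaller than the
population the 0.01 convention was designed for; with a 0.01 caliper at
n ≈ 5,000 almost no pairs form.

SMDs use the two-group pooled-variance form with n−1 variances; a
zero-pooled-variance column reports 0 by convention. The ATT odds ratio
is the treatment coefficient of a logistic fit (treatment + covariates)
on matched records with a Wald 95% CI; the ATT risk difference averages
expit contrasts over matched treated units, with a percentile bootstrap
over resampled pairs (default 500 resamples; bootstrap refits that
separate are dropped and counted). A crude matched-sample odds ratio is
emitted alongside the adjusted one, since either may be the quantity a
reader expects.

## Bayesian arm

The joint density is exactly the one displayed in the package docstring
(`ttwcausal.bayes`). Design choices, in order of consequence:

- **Clever covariate (ATE form).** H = A/e − (1−A)/(1−e), recomputed
  inside the density from the current propensity parameters, so the two
  blocks are coupled (no "cut"). A plug-in mode that freezes H at
  externally supplied propensities, and an ATT-weighted form
  H = A − (1−A)e/(1−e), are available as configuration for sensitivity
  analyses. Propensities are clipped to [1e-6, 1−1e-6] inside H, with
  clip counts tracked; gradients are zeroed on clipped records.
- **Regularized horseshoe.** τ₀ defaults to p₀/((p−p₀)√n) with a prior
  guess of p₀ = 5 relevant predictors; slab scale c₀ = 2, slab df
  ν = 4. Coefficients are non-centered (β_j = z_j τ λ̃_j) and all scales
  are sampled on the log scale.
- **Hierarchy.** Subgroup intercept offsets and (optionally, default
  on) per-coefficient offsets are non-centered normals with
  Half-Normal(1) hyper-scales. Single-stratum cohorts automatically
  disable the hierarchy.
- **Other priors.** Intercepts, ψ and φ are N(0, 2.5²).

Sampling is an in-package No-U-Turn sampler: slice-variant tree
doubling, divergence threshold 1000 on the Hamiltonian error,
dual-averaging step-size adaptation, and diagonal mass-matrix
estimation over Stan-style expanding warmup windows. The mass matrix is
seeded with model-informed scale guesses (1/information for
intercept-like parameters, unit scale for non-centered coordinates),
which substantially shortens early-warmup trajectories. The log density
and its analytic gradient are evaluated in a single compiled (numba)
pass; gradient correctness is enforced against central finite
differences at 1e-4 relative tolerance. Split R-hat and bulk ESS come
from arviz; R-hat > 1.01 warns, and a post-warmup divergence rate above
10% raises. For the heavier study-scale runs the maximum tree depth is
capped at 7 (128 leapfrog steps) — at the adapted step size the
trajectories otherwise double once more for little ESS gain; diagnostics
(R-hat ≤ 1.01, ESS, zero divergences) are checked at this setting.

Effects are computed per posterior draw by averaging
p1 = expit(lp_y | A=1, H(1,e)) minus p0 = expit(lp_y | A=0, H(0,e))
over the filtered cohort; the headline odds ratio is the marginal one
from the averaged potential-outcome probabilities (comparable across
arms), with the conditional exp(ψ + φ(H(1,ē)−H(0,ē))) reported
descriptively. Intervals are central 95% credible regions.

## Model evaluation

PSIS-LOO: importance ratios 1/p(y_i|θ_s), Pareto-smoothed tails
(standard practice: the largest ~20% of ratios, minimum 5, replaced by
expected order statistics; implementation from arviz), k̂ recorded per
record with 0.7 as the warning threshold. The LOO predictive
probability of y_i = 1 feeds a Mann-Whitney AUROC (ties count half) for
each of the two response blocks, since the analysis treats both
treatment participation and benefit suspension as modeled outcomes.

## Problem sizes and numerical settings used in the shipped analyses

- Population marginals: n = 100,000 (one generation).
- Matched frequentist analysis: n = 20,000 cohort, SSDI/physical-RFC
  stratum (the largest), caliper 0.1 (logit), 200 bootstrap
  pair-resamples.
- Doubly robust analyses: n = 5,000, 4 chains × (400 warmup + 1,000
  kept draws), target acceptance 0.8, max tree depth 7. The
  double-robustness checks compare |DR − true ATE| against 3 posterior
  SDs and the crude contrast against 3 of its standard errors.
- Coverage study: 100 replicates at n = 5,000, Wald 95% CIs for the
  matched-sample odds ratio against the true conditional OR of 4. At
  this size the cohort is matched as a whole with program and RFC
  availability as covariates, and post-matching adjustment uses the
  substantive covariates only: per-stratum matching with the full
  covariate set leaves ~80 pairs against ~25 parameters, a regime where
  the logistic MLE's sparse-data bias and quasi-separation dominate and
  no Wald interval is trustworthy. Predictor sets are configuration
  throughout.
- Shrinkage check: n = 2,000 with 2 strong (|coef| = 1.5) and 20 null
  predictors; null posterior means must average below a quarter of the
  strong ones in absolute value.

These sizes are the package's chosen study conditions for synthetic
validation; all are parameters, not constants.

## Known limitations

- The generator matches published marginals only; joint dependence is
  product-form within the covariate block.
- The Bayesian arm's functional form (linear predictors, prior scales,
  hierarchy placement) is one defensible reconstruction of a
  "hierarchical joint model with regularized horseshoe priors and a
  clever covariate"; alternatives (e.g. coefficient-specific pooling
  structures) would be equally consistent with that description.
- Matched-pair bootstrap intervals ignore propensity-estimation
  uncertainty, as is conventional.
- No multiple imputation; missingness is handled by indicator columns
  in both arms.
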