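# ttwcausal

Two-arm causal inference for disability-benefit cohorts: does
participation in an employment-support program (a "Ticket" assigned to
SSI/SSDI beneficiaries) increase the probability that benefits are later
suspended or terminated because of work?

The administrative data this design targets are confidential, so the
package ships a **synthetic-cohort generator** that emulates the
published marginal structure of such a population — program mixture
(SSI / SSDI / Concurrent), residual-functional-capacity assessment
availability (47.12% physical-only / 42.78% mental-only / 10.10% both),
~5.1% treatment prevalence, ~11.2% outcome prevalence, covariate-driven
confounding of both treatment and outcome, and >25% missingness in three
of four mental-function domains — while exposing every record's true
propensity and potential-outcome probabilities. Every analysis stage is
therefore testable against known ground truth.

## The two arms

**Frequentist propensity-score matching.** Within strata defined by
program and RFC availability, the propensity e(X) = P(A=1|X) is
estimated by logistic regression; treated records are matched 1:1
without replacement to their nearest control on the logit of the
propensity score subject to a caliper (default 0.01, absolute on the
logit scale); balance is checked with standardized mean differences
SMD = (x̄_T − x̄_C)/√((s²_T + s²_C)/2); and the ATT is estimated on the
matched sample — a covariate-adjusted treatment odds ratio with a Wald
interval, and the risk difference mean[expit(lp|A=1) − expit(lp|A=0)]
over matched treated units with a pair-resampling bootstrap interval.

**Bayesian doubly robust joint model.** One hierarchical posterior over
all records models treatment and outcome simultaneously:

    A_i ~ Bernoulli(expit(α_g + x_i'(β + δ_g)))
    Y_i ~ Bernoulli(expit(γ_g + x_i'(θ + η_g) + ψ A_i + φ H_i))

with the *clever covariate* H(A, e) = A/e − (1−A)/(1−e) recomputed from
the current propensity parameters inside the density. Including H makes
the average treatment effect doubly robust: consistent when either the
treatment model or the outcome model is correctly specified.
Regularized horseshoe priors shrink β and θ (local scales λ_j ~ C⁺(0,1),
global scale τ ~ C⁺(0, τ₀), slab c² ~ Inv-Gamma(ν/2, νc₀²/2)); subgroup
offsets are partially pooled. Sampling is adaptive Hamiltonian Monte
Carlo (an in-package NUTS with analytic gradients); model
generalizability is scored by leave-one-out cross-validated AUROC via
Pareto-smoothed importance sampling.

## Worked example

```python
import ttwcausal as t
from ttwcausal.bayes import JointModelSpec, build_joint_model, sample_posterior, dr_effect
from ttwcausal.cohort import confounded_scenario, oracle_effects

sc = confounded_scenario(n_records=5000, seed=13)   # known truth
cohort, truth = t.generate_cohort(sc)
print(oracle_effects(sc, 200_000).true_ate)          # 0.1308

# frequentist arm on the (single) stratum
dm = t.build_design(cohort, ("SSI", "PRFC"))
fit = t.fit_logistic(dm, "treatment")
m = t.match(fit, caliper=0.1)
att = t.att_estimate(dm, m, n_boot=200, seed=1)
print(att.odds_ratio.point)                          # 2.103 (true conditional OR = 2.0)

# Bayesian arm, outcome model deliberately missing the "severity" confounder
spec = JointModelSpec(chains=4, warmup=400, draws=1000, seed=2,
                      max_treedepth=7, outcome_drop=("severity",))
post = sample_posterior(build_joint_model(t.pool_design(cohort), spec), spec)
rd = dr_effect(post)["risk-difference"]
print(rd.point, rd.extras["posterior_sd"])           # 0.1378, 0.0194  — within
                                                     # 0.4 posterior SD of truth,
                                                     # while the crude contrast
                                                     # (0.2218) is ~4.7 SE off
```

The numbers shown are from a run with these exact seeds; the doubly
robust estimate stays near the true ATE (0.1308) despite the broken
outcome model because the propensity block, through H, absorbs the
confounding.

A command-line pipeline mirrors the library:

```sh
ttw simulate --n 20000 --seed 0 --out cohort.csv
ttw psm   --cohort cohort.csv --stratum SSI:MRFC --caliper 0.01 --out psm/
ttw bayes --cohort cohort.csv --chains 4 --draws 1000 --seed 0 --out bayes/
ttw loo   --draws bayes/ --out loo.csv
ttw report --in . --out report/
```

All stages write plain delimited text and are byte-identical under a
fixed seed.

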