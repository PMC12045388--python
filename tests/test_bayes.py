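"""Joint model: density oracle, clever covariate, sampling contracts."""

import math

import numpy as np
import pytest
from scipy.special import expit

import ttwcausal as t
from ttwcausal.bayes import (
    JointModelSpec,
    build_joint_model,
    clever_covariate,
    dr_effect,
    sample_posterior,
)
from ttwcausal.design import DesignMatrix

from conftest import make_scenario


def _pooled(n=3, p=0, A=None, Y=None, X=None, groups=None, G=1):
    A = np.asarray(A if A is not None else np.zeros(n), np.int64)
    Y = np.asarray(Y if Y is not None else np.zeros(n), np.int64)
    X = np.asarray(X if X is not None else np.zeros((n, p)), float)
    gi = np.asarray(groups if groups is not None else np.zeros(n), np.int64)
    return DesignMatrix(
        row_ids=np.array([f"R{i}" for i in range(n)]),
        columns=[f"x{j}" for j in range(X.shape[1])],
        X=X,
        treatment=A,
        outcome=Y,
        subgroup_labels=[f"g{k}" for k in range(G)],
        subgroup_index=gi,
    )


FAST = dict(chains=2, warmup=200, draws=500)


class TestCleverCovariate:
    @pytest.mark.parametrize(
        "a,e,expected",
        [(1, 0.5, 2.0), (0, 0.5, -2.0), (1, 0.2, 5.0), (0, 0.2, -1.25)],
    )
    def test_ate_form_values(self, a, e, expected):
        assert clever_covariate(a, e) == pytest.approx(expected)

    def test_clipping_absorbs_extremes(self):
        h = clever_covariate(np.array([1.0]), np.array([0.0]))
        assert np.isfinite(h).all()
        assert h[0] == pytest.approx(1e6)

    def test_att_form(self):
        assert clever_covariate(1, 0.2, form="att") == pytest.approx(1.0)
        assert clever_covariate(0, 0.2, form="att") == pytest.approx(-0.25)


class TestJointDensity:
    def test_all_zero_parameters_hand_computed(self):
        # 3 records, no predictors, no hierarchy: at zero parameters both
        # likelihood blocks are Bernoulli(1/2), so the log-likelihood is
        # 6 ln(1/2); the only non-constant prior terms vanish at zero.
        dm = _pooled(n=3, A=[1, 0, 1], Y=[0, 0, 1])
        spec = JointModelSpec(**FAST, hierarchy=False, clever_covariate=False)
        model = build_joint_model(dm, spec)
        x = np.zeros(model.dim)
        expected = 6 * math.log(0.5)  # priors contribute 0 at the origin
        assert model.logpdf(x) == pytest.approx(expected, abs=1e-12)

    def test_clever_covariate_term_enters_density(self):
        dm = _pooled(n=2, A=[1, 0], Y=[1, 0])
        spec = JointModelSpec(**FAST, hierarchy=False)
        model = build_joint_model(dm, spec)
        x = np.zeros(model.dim)
        x[model.layout.slices["phi"]] = 0.3
        # at zero propensity params e = 1/2, so H = (2, -2)
        lp_y = np.array([0.3 * 2.0, 0.3 * -2.0])
        expected = (
            2 * math.log(0.5)  # treatment block
            + (lp_y[0] - np.logaddexp(0, lp_y[0]))  # y=1
            + (-np.logaddexp(0, lp_y[1]))  # y=0
            - 0.5 * (0.3 / 2.5) ** 2
        )
        assert model.logpdf(x) == pytest.approx(float(expected), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        sc = make_scenario(n_records=150, seed=8)
        cohort, _ = t.generate_cohort(sc)
        dm = t.pool_design(cohort)
        model = build_joint_model(dm, JointModelSpec(**FAST))
        for _ in range(20):
            x = model.initial_position(rng) + 0.4 * rng.standard_normal(model.dim)
            _, g = model.logp_and_grad(x)
            for j in rng.choice(model.dim, size=8, replace=False):
                xp, xm = x.copy(), x.copy()
                xp[j] += 1e-5
                xm[j] -= 1e-5
                fd = (model.logpdf(xp) - model.logpdf(xm)) / 2e-5
                assert abs(fd - g[j]) / max(1.0, abs(fd)) < 1e-4

    def test_reduces_to_plain_bayesian_logistic(self):
        # phi = 0, no hierarchy: the treatment block's contribution equals
        # an independently written horseshoe-logistic density on any point
        rng = np.random.default_rng(4)
        n, p = 60, 2
        X = rng.binomial(1, 0.5, (n, p)).astype(float)
        A = rng.binomial(1, 0.4, n)
        dm = _pooled(n=n, A=A, X=X)
        spec = JointModelSpec(
            **FAST, hierarchy=False, clever_covariate=False, outcome_drop=("x0", "x1")
        )
        model = build_joint_model(dm, spec)
        lay = model.layout

        def independent_density(x):
            # direct transcription of the treatment block density
            a0 = x[lay.slices["t.intercept"]][0]
            seg = x[lay.slices["t.hs"]]
            z, llam = seg[:p], seg[p : 2 * p]
            lam, tau, c2 = np.exp(llam), math.exp(seg[2 * p]), math.exp(seg[2 * p + 1])
            m = tau * lam * math.sqrt(c2) / np.sqrt(c2 + tau**2 * lam**2)
            beta = z * m
            lp = a0 + X @ beta
            ll = float(A @ lp - np.logaddexp(0, lp).sum())
            tau0 = model.hs_t.tau0
            pri = -0.5 * float(z @ z)
            pri += float(np.sum(-np.log1p(lam**2) + llam))
            pri += -math.log1p((tau / tau0) ** 2) + seg[2 * p]
            nu, c0 = spec.nu, spec.c0
            pri += -(nu / 2) * seg[2 * p + 1] - (nu * c0**2 / 2) / c2
            pri += -0.5 * (a0 / 2.5) ** 2
            return ll + pri

        for _ in range(5):
            x = 0.5 * rng.standard_normal(model.dim)
            # zero out the outcome block so it contributes a known constant
            x[lay.slices["y.intercept"]] = 0.0
            x[lay.slices["psi"]] = 0.0
            got = model.logpdf(x)
            want = independent_density(x) + n * math.log(0.5)
            assert got == pytest.approx(want, abs=1e-10)


class TestSampling:
    def test_intercept_only_matches_grid_posterior(self):
        # 40 successes in 100: compare E[expit(a)] with a brute-force
        # 1-D grid posterior under the same N(0, 2.5^2) prior
        A = np.r_[np.ones(40), np.zeros(60)].astype(int)
        dm = _pooled(n=100, A=A)
        spec = JointModelSpec(**FAST, hierarchy=False, clever_covariate=False, seed=3)
        model = build_joint_model(dm, spec)
        post = sample_posterior(model, spec)
        a_draws = post.scalar("t.intercept")

        grid = np.linspace(-3, 3, 4001)
        loglik = 40 * grid - 100 * np.logaddexp(0, grid) - 0.5 * (grid / 2.5) ** 2
        w = np.exp(loglik - loglik.max())
        w /= w.sum()
        grid_mean = float(np.sum(w * expit(grid)))
        ess = float(post.ess["t.intercept"])
        mc_se = float(expit(a_draws).std() / math.sqrt(max(ess, 10.0)))
        assert abs(expit(a_draws).mean() - grid_mean) < 3 * mc_se

    def test_fixed_seed_reproducible(self):
        dm = _pooled(n=50, A=np.tile([1, 0], 25), Y=np.tile([0, 1], 25))
        spec = JointModelSpec(**FAST, hierarchy=False, seed=11)
        a = sample_posterior(build_joint_model(dm, spec), spec)
        b = sample_posterior(build_joint_model(dm, spec), spec)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="chains"):
            JointModelSpec(chains=1)
        with pytest.raises(ValueError, match="500"):
            JointModelSpec(draws=100)
        with pytest.raises(ValueError, match="positive"):
            JointModelSpec(tau0=-1.0)


class TestDrEffect:
    def test_point_mass_null_draws(self):
        dm = _pooled(n=4, A=[1, 0, 1, 0], Y=[1, 0, 0, 1])
        spec = JointModelSpec(**FAST, hierarchy=False)
        model = build_joint_model(dm, spec)
        draws = np.zeros((2, 500, model.dim))
        post = t.PosteriorDraws(
            model=model,
            draws=draws,
            rhat=None,
            ess=None,
            divergence_rate=0.0,
        )
        eff = dr_effect(post)
        assert eff["risk-difference"].point == pytest.approx(0.0, abs=1e-12)
        assert eff["odds-ratio"].point == pytest.approx(1.0, abs=1e-12)

    def test_single_record_hand_computed(self):
        dm = _pooled(n=1, A=[1], Y=[1])
        spec = JointModelSpec(**FAST, hierarchy=False)
        model = build_joint_model(dm, spec)
        x = np.zeros(model.dim)
        lay = model.layout
        x[lay.slices["t.intercept"]] = 0.4
        x[lay.slices["y.intercept"]] = -0.3
        x[lay.slices["psi"]] = 0.7
        x[lay.slices["phi"]] = 0.1
        post = t.PosteriorDraws(
            model=model, draws=np.tile(x, (2, 500, 1)), rhat=None, ess=None, divergence_rate=0.0
        )
        e = expit(0.4)
        p1 = expit(-0.3 + 0.7 + 0.1 * (1 / e))
        p0 = expit(-0.3 + 0.1 * (-1 / (1 - e)))
        eff = dr_effect(post)
        assert eff["risk-difference"].point == pytest.approx(p1 - p0, abs=1e-12)

    def test_empty_filter_rejected(self):
        dm = _pooled(n=2, A=[1, 0], Y=[0, 1])
        spec = JointModelSpec(**FAST, hierarchy=False)
        model = build_joint_model(dm, spec)
        post = t.PosteriorDraws(
            model=model, draws=np.zeros((2, 500, model.dim)), rhat=None, ess=None, divergence_rate=0.0
        )
        with pytest.raises(ValueError):
            dr_effect(post, np.zeros(2, bool))


class TestModelProperties:
    def test_joint_treatment_block_matches_separate_fit(self):
        # with the clever covariate off and no hierarchy the posterior
        # factorizes: the joint model's treatment block must agree with an
        # independently sampled single-block horseshoe logistic regression
        rng = np.random.default_rng(14)
        n, p = 400, 3
        X = rng.binomial(1, 0.5, (n, p)).astype(float)
        A = rng.binomial(1, expit(-0.5 + 1.0 * X[:, 0]), n)
        Y = rng.binomial(1, 0.3, n)
        dm = _pooled(n=n, A=A, Y=Y, X=X)
        spec = JointModelSpec(chains=2, warmup=300, draws=800, seed=15, hierarchy=False,
                              clever_covariate=False)
        joint = build_joint_model(dm, spec)
        post_joint = sample_posterior(joint, spec)
        beta_joint = joint.coef_draws(post_joint.flat, "t")

        from ttwcausal.bayes import HorseshoeLogistic

        solo = HorseshoeLogistic(X, A, JointModelSpec(chains=2, warmup=300, draws=800, seed=16))
        post_solo = sample_posterior(solo, solo.spec)
        beta_solo = solo.coef_draws(post_solo.flat, "t")
        for j in range(p):
            se = math.hypot(
                beta_joint[:, j].std() / math.sqrt(100), beta_solo[:, j].std() / math.sqrt(100)
            )  # conservative effective-sample allowance
            assert abs(beta_joint[:, j].mean() - beta_solo[:, j].mean()) < 4 * se

    def test_partial_pooling_lies_between_extremes(self):
        # two strata with different treatment rates: the hierarchical
        # estimate of each group intercept sits between the no-pooling
        # (per-group empirical) and complete-pooling (overall) values
        rng = np.random.default_rng(20)
        n = 1600
        g = np.repeat([0, 1], n // 2)
        rate = np.where(g == 0, 0.15, 0.45)
        A = rng.binomial(1, rate)
        dm = _pooled(n=n, A=A, Y=rng.binomial(1, 0.3, n), groups=g, G=2)
        spec = JointModelSpec(chains=2, warmup=300, draws=600, seed=21, clever_covariate=False)
        post = sample_posterior(build_joint_model(dm, spec), spec)
        a0 = post.scalar("t.intercept")
        u0 = post.model.layout.get(post.flat, "t.u0")
        sig0 = np.exp(post.scalar("t.lsig0"))
        pooled = float(np.log(A.mean() / (1 - A.mean())))
        for k in range(2):
            group_lp = float(np.mean(a0 + sig0 * u0[:, k]))
            no_pool = float(np.log(A[g == k].mean() / (1 - A[g == k].mean())))
            lo, hi = sorted([no_pool, pooled])
            assert lo - 0.05 <= group_lp <= hi + 0.05

    def test_posterior_sd_shrinks_with_sample_size(self):
        # doubling n should shrink sd(psi) by about sqrt(2)
        from ttwcausal.cohort import confounded_scenario
        import dataclasses

        sds = {}
        base = confounded_scenario(n_records=1500, seed=30)
        for n in (1500, 3000):
            sc = dataclasses.replace(base, n_records=n, seed=30)
            cohort, _ = t.generate_cohort(sc)
            spec = JointModelSpec(chains=2, warmup=300, draws=500, seed=31, max_treedepth=7)
            post = sample_posterior(build_joint_model(t.pool_design(cohort), spec), spec)
            sds[n] = float(post.scalar("psi").std())
        ratio = sds[1500] / sds[3000]
        assert abs(ratio - math.sqrt(2)) < 0.2 * math.sqrt(2)
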