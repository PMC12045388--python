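"""Frequentist arm: logistic MLE, caliper matching, balance, ATT."""

import math

import numpy as np
import pytest

import ttwcausal as t
from ttwcausal.design import DesignMatrix
from ttwcausal.psm import SeparationError, att_estimate, balance, fit_logistic, match

from conftest import make_scenario


def _design(X, treatment, outcome=None, ids=None, columns=None):
    n, p = X.shape
    return DesignMatrix(
        row_ids=np.asarray(ids if ids is not None else [f"R{i:04d}" for i in range(n)]),
        columns=list(columns or [f"x{j}" for j in range(p)]),
        X=np.asarray(X, float),
        treatment=np.asarray(treatment, np.int64),
        outcome=np.asarray(outcome if outcome is not None else np.zeros(n), np.int64),
        subgroup="test",
    )


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        dm = _design(np.empty((100, 0)), y)
        fit = fit_logistic(dm, "treatment")
        assert fit.coef("(intercept)") == pytest.approx(math.log(40 / 60), abs=1e-6)

    def test_two_by_two_closed_form(self):
        # counts (a,b,c,d) = (20,30,10,40): slope = ln(ad/bc) = ln(8/3)
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(20), np.zeros(30), np.ones(10), np.zeros(40)]
        fit = fit_logistic(_design(x[:, None], y, columns=["x"]), "treatment")
        assert fit.coef("x") == pytest.approx(math.log(20 * 40 / (30 * 10)), abs=1e-6)
        assert fit.coef("(intercept)") == pytest.approx(math.log(10 / 40), abs=1e-6)

    def test_logits_match_scores(self, confounded_cohort):
        _, cohort, _ = confounded_cohort
        fit = fit_logistic(t.pool_design(cohort), "treatment")
        from scipy.special import logit

        np.testing.assert_allclose(fit.logits, logit(fit.scores), atol=1e-10)
        assert fit.converged

    def test_simulation_consistency(self):
        rng = np.random.default_rng(3)
        n = 50_000
        X = rng.binomial(1, 0.4, size=(n, 2)).astype(float)
        lp = -1.0 + 0.7 * X[:, 0] - 0.5 * X[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        fit = fit_logistic(_design(X, y, columns=["a", "b"]), "treatment")
        assert abs(fit.coef("a") - 0.7) < 3 * fit.se("a")
        assert abs(fit.coef("b") - (-0.5)) < 3 * fit.se("b")

    def test_separation_raises(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(SeparationError):
            fit_logistic(_design(x[:, None], x), "treatment")

    def test_no_variation_raises(self):
        dm = _design(np.random.default_rng(0).normal(size=(20, 1)), np.ones(20))
        with pytest.raises(ValueError, match="variation"):
            fit_logistic(dm, "treatment")


def _fit_from_logits(logits, treatment, ids=None):
    """A converged PropensityFit stub with prescribed logits."""
    from scipy.special import expit

    n = len(logits)
    return t.PropensityFit(
        columns=["(intercept)"],
        params=np.zeros(1),
        bse=np.ones(1),
        scores=expit(np.asarray(logits, float)),
        logits=np.asarray(logits, float),
        converged=True,
        loglik=0.0,
        response=np.asarray(treatment, np.int64),
        row_ids=np.asarray(ids if ids is not None else [f"R{i:04d}" for i in range(n)]),
    )


def _greedy_oracle(logits, treatment, ids, caliper):
    """Brute-force matcher: same greedy order, exhaustive nearest search."""
    treated = sorted(
        [i for i in range(len(logits)) if treatment[i] == 1], key=lambda i: (-logits[i], ids[i])
    )
    controls = [i for i in range(len(logits)) if treatment[i] == 0]
    used = set()
    pairs, unmatched = [], []
    for ti in treated:
        best = None
        for ci in controls:
            if ci in used:
                continue
            cand = (abs(logits[ci] - logits[ti]), ids[ci], ci)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] > caliper:
            unmatched.append(ids[ti])
            continue
        used.add(best[2])
        pairs.append((ids[ti], best[1], best[0]))
    return pairs, unmatched


class TestMatch:
    def test_identical_logits_pair_at_distance_zero(self):
        fit = _fit_from_logits([0.3, 0.3], [1, 0])
        m = match(fit)
        assert m.n_pairs == 1
        assert m.pairs.loc[0, "logit_distance"] == 0.0

    def test_caliper_excludes_distant_control(self):
        fit = _fit_from_logits([0.0, 0.02], [1, 0])
        m = match(fit, caliper=0.01)
        assert m.n_pairs == 0
        assert list(m.unmatched_treated) == ["R0000"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for rep in range(50):
            n = int(rng.integers(4, 31))
            logits = np.round(rng.normal(size=n), 2)  # rounding forces ties
            treatment = rng.binomial(1, 0.4, size=n)
            if treatment.sum() in (0, n):
                continue
            ids = [f"R{i:04d}" for i in range(n)]
            caliper = float(rng.choice([0.05, 0.2, 1.0]))
            m = match(_fit_from_logits(logits, treatment, ids), caliper=caliper)
            pairs, unmatched = _greedy_oracle(logits, treatment, ids, caliper)
            got = list(m.pairs.itertuples(index=False, name=None))
            assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in pairs]
            assert list(m.unmatched_treated) == unmatched
            # contract: injective, within caliper
            assert m.pairs["control_id"].is_unique and m.pairs["treated_id"].is_unique
            assert (m.pairs["logit_distance"] <= caliper + 1e-12).all()

    def test_caliper_monotonicity(self, confounded_cohort):
        _, cohort, _ = confounded_cohort
        fit = fit_logistic(t.pool_design(cohort), "treatment")
        sizes = [match(fit, caliper=c).n_pairs for c in (0.001, 0.01, 0.1, 1.0)]
        assert sizes == sorted(sizes)
        n_treated = int(fit.response.sum())
        assert all(s <= n_treated for s in sizes)

    def test_bad_caliper(self):
        fit = _fit_from_logits([0.0, 0.1], [1, 0])
        with pytest.raises(ValueError, match="caliper"):
            match(fit, caliper=0.0)


class TestBalance:
    def test_identical_groups_zero_smd(self):
        X = np.tile(np.array([[1.0], [0.0]]), (5, 1))
        a = np.r_[np.ones(5), np.zeros(5)]
        X = np.r_[X[:5], X[:5]]
        dm = _design(X, a)
        fit = _fit_from_logits(np.zeros(10), a)
        m = match(fit, caliper=1.0)
        rep = balance(dm, m)
        assert (rep.table["smd_before"] == 0).all()
        assert (rep.table["smd_after"] == 0).all()

    def test_formula_against_direct_evaluation(self):
        rng = np.random.default_rng(5)
        x_t = rng.binomial(1, 0.5, 4000).astype(float)
        x_c = rng.binomial(1, 0.3, 4000).astype(float)
        X = np.r_[x_t, x_c][:, None]
        a = np.r_[np.ones(4000), np.zeros(4000)]
        dm = _design(X, a)
        m = match(_fit_from_logits(np.zeros(8000), a), caliper=1.0)
        rep = balance(dm, m)
        expected = (x_t.mean() - x_c.mean()) / math.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2)
        assert rep.table.loc[0, "smd_before"] == pytest.approx(expected, abs=1e-12)
        # population value ~ 0.2 / sqrt((0.25 + 0.21)/2)
        assert rep.table.loc[0, "smd_before"] == pytest.approx(0.2 / math.sqrt(0.23), abs=0.1)

    def test_exact_matched_duplicates_zero_smd_after(self, confounded_cohort):
        _, cohort, _ = confounded_cohort
        treated = cohort[cohort["treatment"] == 1].copy()
        clones = treated.copy()
        clones["treatment"] = 0
        clones["record_id"] = "C" + clones["record_id"].str.lstrip("R")
        import pandas as pd

        both = pd.concat([treated, clones], ignore_index=True)
        dm = t.pool_design(both)
        logits = np.tile(np.linspace(-1, 1, len(treated)), 2)
        fit = _fit_from_logits(logits, both["treatment"].to_numpy(), both["record_id"].to_numpy())
        m = match(fit, caliper=1e-9)
        rep = balance(dm, m)
        assert m.n_pairs == len(treated)
        assert np.allclose(rep.table["smd_after"], 0.0)


class TestAttEstimate:
    def test_unconfounded_recovers_truth(self):
        sc = make_scenario(
            n_records=6000,
            seed=31,
            propensity=t.LinearModel(-1.5),  # no confounding of treatment
            true_treatment_logor=math.log(3.0),
        )
        cohort, truth = t.generate_cohort(sc)
        dm = t.pool_design(cohort)
        fit = fit_logistic(dm, "treatment")
        m = match(fit, caliper=0.2)
        res = att_estimate(dm, m, n_boot=100, seed=2)
        se = res.risk_difference.extras["bootstrap_se"]
        assert abs(res.risk_difference.point - truth.true_att) < 3 * se
        # unconfounded: crude and adjusted matched ORs agree
        assert res.crude_odds_ratio.point == pytest.approx(res.odds_ratio.point, rel=0.35)

    def test_outcome_equals_treatment_separates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 1))
        a = np.r_[np.ones(20), np.zeros(20)]
        dm = _design(X, a, outcome=a)
        m = match(_fit_from_logits(np.round(rng.normal(size=40), 1), a), caliper=5.0)
        with pytest.raises((SeparationError, ValueError)):
            att_estimate(dm, m, n_boot=0)

    def test_requires_pairs(self):
        fit = _fit_from_logits([0.0, 5.0], [1, 0])
        m = match(fit, caliper=0.01)
        dm = _design(np.zeros((2, 0)), [1, 0])
        with pytest.raises(ValueError, match="pairs"):
            att_estimate(dm, m)
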