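"""Bayesian doubly robust arm: hierarchical joint treatment/outcome model.

One posterior covers every record exactly once. Treatment assignment
(the propensity model) and the outcome are modeled simultaneously as two
Bernoulli likelihoods sharing a hierarchy over (program, rfc) strata:

    A_i ~ Bernoulli( expit( a_g(i) + x_i' (beta + delta_g(i)) ) )
    Y_i ~ Bernoulli( expit( c_g(i) + x_i' (theta + eta_g(i))
                            + psi A_i + phi H_i ) )

H_i is the *clever covariate* H(A, e) = A/e - (1-A)/(1-e), recomputed
inside the density from the current propensity parameters, so treatment
and outcome information flow both ways. Including H makes the average
treatment effect doubly robust: it is consistent when either the
propensity block or the outcome block is correctly specified.

Regularized horseshoe priors shrink the regression coefficients: with
local scales lambda_j ~ C+(0,1), global scale tau ~ C+(0, tau0) and slab
c^2 ~ Inv-Gamma(nu/2, nu c0^2 / 2),

    beta_j ~ N(0, tau^2 lambda_tilde_j^2),
    lambda_tilde_j^2 = c^2 lambda_j^2 / (c^2 + tau^2 lambda_j^2).

Coefficients are parameterized non-centered (beta_j = z_j tau
lambda_tilde_j, z_j ~ N(0,1)) and all scales on the log scale, so the
sampler sees an unconstrained space. Subgroup offsets are non-centered
normals with Half-Normal(1) hyper-scales (partial pooling). Intercepts,
psi and phi carry weakly informative N(0, 2.5^2) priors.

Sampling uses the in-package NUTS implementation; split R-hat and bulk
ESS come from arviz.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignMatrix
from .effects import EffectEstimate
from ._kernels import joint_logp_grad
from .hmc import run_nuts

logger = logging.getLogger(__name__)

__all__ = [
    "PROPENSITY_CLIP",
    "JointModelSpec",
    "JointModel",
    "HorseshoeLogistic",
    "PosteriorDraws",
    "DivergenceError",
    "clever_covariate",
    "build_joint_model",
    "sample_posterior",
    "dr_effect",
]

PROPENSITY_CLIP = 1e-6
_SCALE_INTERCEPT = 2.5


class DivergenceError(RuntimeError):
    """More than 10% of post-warmup transitions diverged.

    Consider a smaller step size (higher target_accept), more warmup, or
    a reparameterization.
    """


def clever_covariate(treatment, propensity, form: str = "ate"):
    """Clever covariate H(A, e) used for doubly robust adjustment.

    ATE form: H = A/e - (1-A)/(1-e). ATT form (sensitivity option):
    H = A - (1-A) e/(1-e). Propensities are clipped to
    [1e-6, 1 - 1e-6]; the number of clipped values is logged.
    """
    a = np.asarray(treatment, float)
    e = np.asarray(propensity, float)
    n_clip = int(np.sum((e < PROPENSITY_CLIP) | (e > 1 - PROPENSITY_CLIP)))
    if n_clip:
        logger.info("clever_covariate: clipped %d propensity values", n_clip)
    e = np.clip(e, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
    if form == "ate":
        return a / e - (1 - a) / (1 - e)
    if form == "att":
        return a - (1 - a) * e / (1 - e)
    raise ValueError("form must be 'ate' or 'att'")


@dataclass(frozen=True)
class JointModelSpec:
    """Hierarchy, horseshoe hyperparameters and sampler settings.

    ``tau0`` defaults to the standard recommendation
    p0 / ((p - p0) sqrt(n)) with a prior guess of ``p0_guess`` relevant
    predictors; ``c0`` (slab scale) and ``nu`` (slab df) default to 2 and
    4. ``clever_covariate=False`` drops the phi H term (the naive joint
    model); ``att_weighting`` switches H to the ATT form;
    ``plugin_propensity`` freezes H at externally supplied propensities
    instead of coupling the two blocks.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    tau0: float | None = None
    c0: float = 2.0
    nu: float = 4.0
    p0_guess: float = 5.0
    hierarchy: bool = True
    coef_hierarchy: bool = True
    clever_covariate: bool = True
    att_weighting: bool = False
    plugin_propensity: bool = False
    propensity_drop: tuple = ()
    outcome_drop: tuple = ()

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.draws < 500:
            raise ValueError("at least 500 kept draws per chain are required")
        if self.c0 <= 0 or (self.tau0 is not None and self.tau0 <= 0):
            raise ValueError("tau0 and c0 must be positive")

    def resolved_tau0(self, p: int, n: int) -> float:
        if self.tau0 is not None:
            return self.tau0
        p0 = min(self.p0_guess, max(p / 2.0, 1.0))
        return p0 / max(p - p0, 1.0) / math.sqrt(max(n, 2))


# ---------------------------------------------------------------------------
# Horseshoe block: non-centered regularized horseshoe over p coefficients


class _HorseshoeBlock:
    """Parameters (z, log lambda, log tau, log c^2) -> beta, with priors."""

    def __init__(self, p: int, tau0: float, c0: float, nu: float):
        self.p = p
        self.tau0 = tau0
        self.a_ig = nu / 2.0
        self.b_ig = nu * c0**2 / 2.0
        self.size = 2 * p + 2 if p > 0 else 0

    def decode(self, seg: np.ndarray) -> dict:
        p = self.p
        z = seg[:p]
        lam = np.exp(seg[p : 2 * p])
        tau = math.exp(seg[2 * p])
        c2 = math.exp(seg[2 * p + 1])
        s = c2 + tau**2 * lam**2
        m = tau * lam * math.sqrt(c2) / np.sqrt(s)  # tau * lambda_tilde
        return {"z": z, "lam": lam, "tau": tau, "c2": c2, "s": s, "m": m, "beta": z * m}


# ---------------------------------------------------------------------------
# Parameter layout


class _Layout:
    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int) -> None:
        self.slices[name] = slice(self.dim, self.dim + size)
        self.dim += size

    def __contains__(self, name):
        return name in self.slices

    def get(self, vec: np.ndarray, name: str) -> np.ndarray:
        return vec[..., self.slices[name]]

    def names(self) -> list[str]:
        out = []
        for name, sl in self.slices.items():
            width = sl.stop - sl.start
            if width == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{j}]" for j in range(width))
        return out


# ---------------------------------------------------------------------------
# Joint model


class JointModel:
    """Joint log density with analytic gradient over the pooled design."""

    def __init__(self, design: DesignMatrix, spec: JointModelSpec, fixed_H: np.ndarray | None = None):
        if design.subgroup_index is None:
            raise ValueError("joint model requires a pooled design (use pool_design)")
        self.design = design
        self.spec = spec
        self.A = design.treatment.astype(float)
        self.Y = design.outcome.astype(float)
        self.n = design.n
        self.G = len(design.subgroup_labels)
        self.gidx = design.subgroup_index

        def block_cols(drop):
            cols = [c for c in design.columns if c not in drop]
            unknown = set(drop) - set(design.columns)
            if unknown:
                raise ValueError(f"unknown columns to drop: {sorted(unknown)}")
            return cols

        self.cols_t = block_cols(spec.propensity_drop)
        self.cols_y = block_cols(spec.outcome_drop)
        idx = {c: j for j, c in enumerate(design.columns)}
        self.Xt = np.ascontiguousarray(design.X[:, [idx[c] for c in self.cols_t]], float)
        self.Xy = np.ascontiguousarray(design.X[:, [idx[c] for c in self.cols_y]], float)
        self.pt, self.py = self.Xt.shape[1], self.Xy.shape[1]

        self.hs_t = _HorseshoeBlock(self.pt, spec.resolved_tau0(self.pt, self.n), spec.c0, spec.nu)
        self.hs_y = _HorseshoeBlock(self.py, spec.resolved_tau0(self.py, self.n), spec.c0, spec.nu)

        self.fixed_H = None
        if fixed_H is not None:
            if not spec.plugin_propensity:
                raise ValueError("fixed_H supplied but plugin_propensity is False")
            self.fixed_H = np.asarray(fixed_H, float)
        elif spec.plugin_propensity:
            raise ValueError("plugin_propensity requires fixed_H")

        self.hierarchical = spec.hierarchy and self.G > 1
        self.coef_hier = self.hierarchical and spec.coef_hierarchy

        lay = _Layout()
        lay.add("t.intercept", 1)
        if self.pt:
            lay.add("t.hs", self.hs_t.size)
        if self.hierarchical:
            lay.add("t.u0", self.G)
            lay.add("t.lsig0", 1)
            if self.coef_hier and self.pt:
                lay.add("t.U", self.G * self.pt)
                lay.add("t.lsigU", 1)
        lay.add("y.intercept", 1)
        if self.py:
            lay.add("y.hs", self.hs_y.size)
        if self.hierarchical:
            lay.add("y.u0", self.G)
            lay.add("y.lsig0", 1)
            if self.coef_hier and self.py:
                lay.add("y.U", self.G * self.py)
                lay.add("y.lsigU", 1)
        lay.add("psi", 1)
        if spec.clever_covariate:
            lay.add("phi", 1)
        self.layout = lay
        self.dim = lay.dim

        # per-group row indices for offset gradients
        self.group_rows = [np.flatnonzero(self.gidx == g) for g in range(self.G)]
        self._fixed_H_arr = self.fixed_H if self.fixed_H is not None else np.empty(0)
        self.clip_count = 0

        def _start(name: str) -> int:
            return lay.slices[name].start if name in lay else -1

        self._kernel_idx = (
            _start("t.intercept"), _start("t.hs"), _start("t.u0"), _start("t.lsig0"),
            _start("t.U"), _start("t.lsigU"),
            _start("y.intercept"), _start("y.hs"), _start("y.u0"), _start("y.lsig0"),
            _start("y.U"), _start("y.lsigU"),
            _start("psi"), _start("phi"),
        )

    # -- linear predictors ---------------------------------------------------

    def _block_lp(self, x: np.ndarray, which: str) -> tuple[np.ndarray, dict]:
        X = self.Xt if which == "t" else self.Xy
        hs = self.hs_t if which == "t" else self.hs_y
        p = X.shape[1]
        lay = self.layout
        info: dict = {}
        lp = np.full(self.n, float(lay.get(x, f"{which}.intercept")[0]))
        if p:
            seg = lay.get(x, f"{which}.hs")
            d = hs.decode(seg)
            info["hs"] = d
            info["hs_seg"] = seg
            lp = lp + X @ d["beta"]
        if self.hierarchical:
            u0 = lay.get(x, f"{which}.u0")
            sig0 = math.exp(float(lay.get(x, f"{which}.lsig0")[0]))
            info["u0"], info["sig0"] = u0, sig0
            lp = lp + sig0 * u0[self.gidx]
            if self.coef_hier and p:
                U = lay.get(x, f"{which}.U").reshape(self.G, p)
                sigU = math.exp(float(lay.get(x, f"{which}.lsigU")[0]))
                info["U"], info["sigU"] = U, sigU
                lp = lp + sigU * np.einsum("ij,ij->i", X, U[self.gidx])
        return lp, info

    def propensity(self, x: np.ndarray) -> np.ndarray:
        return expit(self._block_lp(x, "t")[0])

    def _H(self, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Clever covariate and its derivative w.r.t. the propensity logit."""
        clipped = (e < PROPENSITY_CLIP) | (e > 1 - PROPENSITY_CLIP)
        self.clip_count += int(clipped.sum())
        ec = np.clip(e, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
        if self.spec.att_weighting:
            H = self.A - (1 - self.A) * ec / (1 - ec)
            dH = -(1 - self.A) * ec / (1 - ec)
        else:
            H = self.A / ec - (1 - self.A) / (1 - ec)
            dH = -self.A * (1 - ec) / ec - (1 - self.A) * ec / (1 - ec)
        dH = np.where(clipped, 0.0, dH)
        return H, dH

    # -- density -------------------------------------------------------------

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        logp, grad, n_clip = joint_logp_grad(
            np.ascontiguousarray(x, float), self.Xt, self.Xy, self.A, self.Y,
            self.gidx, self.G,
            spec.clever_covariate, spec.att_weighting, self._fixed_H_arr,
            self.hs_t.tau0, self.hs_y.tau0, self.hs_t.a_ig, self.hs_t.b_ig,
            _SCALE_INTERCEPT, *self._kernel_idx,
        )
        self.clip_count += n_clip
        return float(logp), grad

    def logpdf(self, x: np.ndarray) -> float:
        return self.logp_and_grad(x)[0]

    # -- init ----------------------------------------------------------------

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        lay = self.layout
        x = np.zeros(self.dim)
        for which, y, hs, p in (("t", self.A, self.hs_t, self.pt), ("y", self.Y, self.hs_y, self.py)):
            rate = float(np.clip(y.mean(), 0.01, 0.99))
            x[lay.slices[f"{which}.intercept"]] = math.log(rate / (1 - rate))
            if p:
                sl = lay.slices[f"{which}.hs"]
                seg = np.zeros(hs.size)
                seg[:p] = 0.1 * rng.standard_normal(p)
                seg[p : 2 * p] = 0.0
                seg[2 * p] = math.log(hs.tau0)
                seg[2 * p + 1] = math.log(self.spec.c0**2)
                x[sl] = seg
            if self.hierarchical:
                x[lay.slices[f"{which}.u0"]] = 0.01 * rng.standard_normal(self.G)
                x[lay.slices[f"{which}.lsig0"]] = math.log(0.3)
                if self.coef_hier and p:
                    x[lay.slices[f"{which}.U"]] = 0.01 * rng.standard_normal(self.G * p)
                    x[lay.slices[f"{which}.lsigU"]] = math.log(0.3)
        return x

    def initial_inv_mass(self) -> np.ndarray:
        """Prior-informed guesses of posterior variances per coordinate.

        Intercept-like and effect parameters in a logistic model with n
        observations have posterior scales around 1/sqrt(information);
        non-centered coordinates sit near unit scale. Seeding the mass
        matrix with these guesses keeps early-warmup trajectories short.
        """
        lay = self.layout
        v = np.ones(self.dim)
        for which, y in (("t", self.A), ("y", self.Y)):
            rate = float(np.clip(y.mean(), 0.01, 0.99))
            info = self.n * rate * (1 - rate)
            v[lay.slices[f"{which}.intercept"]] = 1.0 / info
            if self.hierarchical:
                v[lay.slices[f"{which}.lsig0"]] = 0.25
                if self.coef_hier and f"{which}.lsigU" in lay:
                    v[lay.slices[f"{which}.lsigU"]] = 0.25
        q = float(np.clip(self.Y.mean(), 0.01, 0.99))
        n_t = max(float(self.A.sum()), 1.0)
        v[lay.slices["psi"]] = 1.0 / (n_t * q * (1 - q))
        if self.spec.clever_covariate:
            e_bar = float(np.clip(self.A.mean(), 0.01, 0.99))
            h2 = self.n * (1.0 / e_bar + 1.0 / (1.0 - e_bar))
            v[lay.slices["phi"]] = 1.0 / (h2 * q * (1 - q))
        return v

    # -- derived quantities over draws ----------------------------------------

    def coef_draws(self, flat: np.ndarray, which: str) -> np.ndarray:
        """Natural-scale regression coefficients (S, p) for one block."""
        hs = self.hs_t if which == "t" else self.hs_y
        p = hs.p
        if p == 0:
            return np.empty((flat.shape[0], 0))
        seg = self.layout.get(flat, f"{which}.hs")
        z = seg[:, :p]
        lam = np.exp(seg[:, p : 2 * p])
        tau = np.exp(seg[:, 2 * p : 2 * p + 1])
        c2 = np.exp(seg[:, 2 * p + 1 : 2 * p + 2])
        m = tau * lam * np.sqrt(c2) / np.sqrt(c2 + tau**2 * lam**2)
        return z * m

    def _lp_draws(self, flat: np.ndarray, which: str, rows: np.ndarray) -> np.ndarray:
        """Linear predictor (S, len(rows)) for one block, minus psi/phi terms."""
        X = (self.Xt if which == "t" else self.Xy)[rows]
        lay = self.layout
        beta = self.coef_draws(flat, which)
        lp = lay.get(flat, f"{which}.intercept") + beta @ X.T
        if self.hierarchical:
            u0 = lay.get(flat, f"{which}.u0")
            sig0 = np.exp(lay.get(flat, f"{which}.lsig0"))
            lp = lp + sig0 * u0[:, self.gidx[rows]]
            if self.coef_hier and X.shape[1]:
                U = lay.get(flat, f"{which}.U").reshape(flat.shape[0], self.G, X.shape[1])
                sigU = np.exp(lay.get(flat, f"{which}.lsigU"))
                own = np.einsum("sip,ip->si", U[:, self.gidx[rows], :], X, optimize=True)
                lp = lp + sigU * own
        return lp

    def potential_probs(self, flat: np.ndarray, rows: np.ndarray):
        """Per-draw (e, p1, p0) over the given rows; chunked over draws."""
        lay = self.layout
        e = expit(self._lp_draws(flat, "t", rows))
        ec = np.clip(e, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
        base = self._lp_draws(flat, "y", rows)
        psi = lay.get(flat, "psi")
        if self.spec.clever_covariate:
            phi = lay.get(flat, "phi")
            if self.spec.att_weighting:
                h1, h0 = np.ones_like(ec), -ec / (1 - ec)
            else:
                h1, h0 = 1.0 / ec, -1.0 / (1 - ec)
            p1 = expit(base + psi + phi * h1)
            p0 = expit(base + phi * h0)
        else:
            p1 = expit(base + psi)
            p0 = expit(base)
        return e, p1, p0

    def pointwise_loglik(self, flat: np.ndarray, which: str) -> np.ndarray:
        """Log p(obs_i | params_s) matrix (S, n) for one response block."""
        if which == "t":
            lp = self._lp_draws(flat, "t", np.arange(self.n))
            y = self.A
        else:
            rows = np.arange(self.n)
            base = self._lp_draws(flat, "y", rows)
            lay = self.layout
            lp = base + lay.get(flat, "psi") * self.A
            if self.spec.clever_covariate:
                et = expit(self._lp_draws(flat, "t", rows))
                ec = np.clip(et, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
                if self.spec.att_weighting:
                    H = self.A - (1 - self.A) * ec / (1 - ec)
                else:
                    H = self.A / ec - (1 - self.A) / (1 - ec)
                lp = lp + lay.get(flat, "phi") * H
            y = self.Y
        return y * lp - np.logaddexp(0.0, lp)

    def predictive_prob(self, flat: np.ndarray, which: str) -> np.ndarray:
        """Per-draw P(response_i = 1) matrix (S, n)."""
        ll = self.pointwise_loglik(flat, which)
        y = self.A if which == "t" else self.Y
        # ll is log p(y_i); convert to log p(1)
        p_obs = np.exp(ll)
        return np.where(y == 1, p_obs, 1.0 - p_obs)


class HorseshoeLogistic(JointModel):
    """Single-block Bayesian logistic regression with the same horseshoe.

    Used stand-alone for sparse-regression checks and as the reduction
    target of the joint model (phi = 0, hierarchy off). Implemented as a
    joint model whose outcome block is intercept-only and uncoupled; only
    the treatment block is interpreted.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: JointModelSpec, columns=None):
        n, p = X.shape
        columns = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
        design = DesignMatrix(
            row_ids=np.arange(n),
            columns=columns,
            X=np.asarray(X, float),
            treatment=np.asarray(y, np.int64),
            outcome=np.zeros(n, np.int64),
            subgroup_labels=["all"],
            subgroup_index=np.zeros(n, np.int64),
        )
        spec = JointModelSpec(
            **{
                **{f: getattr(spec, f) for f in spec.__dataclass_fields__},
                "hierarchy": False,
                "clever_covariate": False,
                "outcome_drop": tuple(columns),
            }
        )
        super().__init__(design, spec)


def build_joint_model(
    design: DesignMatrix, spec: JointModelSpec | None = None, fixed_H: np.ndarray | None = None
) -> JointModel:
    """Construct the joint treatment/outcome model over a pooled design."""
    return JointModel(design, spec or JointModelSpec(), fixed_H=fixed_H)


# ---------------------------------------------------------------------------
# Sampling


@dataclass
class PosteriorDraws:
    model: JointModel
    draws: np.ndarray  # (chains, n_draws, dim)
    rhat: pd.Series
    ess: pd.Series
    divergence_rate: float
    step_sizes: list[float] = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def rhat_max(self) -> float:
        return float(self.rhat.max())

    def scalar(self, name: str) -> np.ndarray:
        return self.model.layout.get(self.flat, name)[:, 0]


def sample_posterior(model: JointModel, spec: JointModelSpec | None = None) -> PosteriorDraws:
    """Draw from the joint posterior with NUTS; attach split R-hat / ESS.

    Raises :class:`DivergenceError` if more than 10% of kept transitions
    diverged; warns (without failing) when any split R-hat exceeds 1.01.
    """
    import arviz as az

    spec = spec or model.spec
    ss = np.random.SeedSequence(spec.seed)
    chains = []
    step_sizes = []
    n_div = 0
    for child in ss.spawn(spec.chains):
        rng = np.random.Generator(np.random.PCG64(child))
        x0 = model.initial_position(rng)
        res = run_nuts(
            model.logp_and_grad,
            x0,
            rng,
            n_warmup=spec.warmup,
            n_draws=spec.draws,
            target_accept=spec.target_accept,
            max_treedepth=spec.max_treedepth,
            inv_mass0=model.initial_inv_mass(),
        )
        chains.append(res.positions)
        step_sizes.append(res.step_size)
        n_div += int(res.divergent.sum())
    draws = np.stack(chains)  # (chains, draws, dim)
    div_rate = n_div / (spec.chains * spec.draws)
    if div_rate > 0.10:
        raise DivergenceError(
            f"{100 * div_rate:.1f}% of transitions diverged; "
            "reduce the step size (raise target_accept) or reparameterize"
        )
    names = model.layout.names()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws)
        rhat = np.asarray(az.rhat(ds)["x"])
        ess = np.asarray(az.ess(ds)["x"])
    rhat = pd.Series(rhat, index=names)
    ess = pd.Series(ess, index=names)
    if rhat.max() > 1.01:
        warnings.warn(
            f"max split R-hat {rhat.max():.3f} > 1.01; chains may not have mixed",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorDraws(
        model=model, draws=draws, rhat=rhat, ess=ess, divergence_rate=div_rate, step_sizes=step_sizes
    )


# ---------------------------------------------------------------------------
# Doubly robust effects


def dr_effect(
    draws: PosteriorDraws,
    cohort_filter=None,
    chunk: int = 250,
) -> dict[str, EffectEstimate]:
    """Posterior ATE (risk difference and odds ratio) for a cohort subset.

    ``cohort_filter`` is None (all records), a subgroup label like
    "SSI:MRFC-only", or a boolean row mask. Per draw, every record's
    potential-outcome probabilities p1 and p0 are computed with the
    clever covariate evaluated at H(1, e) and H(0, e); the draw's ATE is
    mean(p1 - p0). The headline odds ratio is the marginal one from the
    averaged potential-outcome probabilities; the conditional odds ratio
    exp(psi + phi (H(1, e-bar) - H(0, e-bar))) is reported descriptively
    in ``extras``.
    """
    model = draws.model
    if cohort_filter is None:
        rows = np.arange(model.n)
        label = "all"
    elif isinstance(cohort_filter, str):
        g = model.design.subgroup_labels.index(cohort_filter)
        rows = np.flatnonzero(model.gidx == g)
        label = cohort_filter
    else:
        rows = np.flatnonzero(np.asarray(cohort_filter))
        label = "subset"
    if len(rows) == 0:
        raise ValueError("cohort filter selects no records")

    flat = draws.flat
    S = flat.shape[0]
    ates = np.empty(S)
    p1m = np.empty(S)
    p0m = np.empty(S)
    ebar = np.empty(S)
    for start in range(0, S, chunk):
        sl = slice(start, min(start + chunk, S))
        e, p1, p0 = model.potential_probs(flat[sl], rows)
        ates[sl] = (p1 - p0).mean(axis=1)
        p1m[sl] = p1.mean(axis=1)
        p0m[sl] = p0.mean(axis=1)
        ebar[sl] = e.mean(axis=1)

    marg_or = (p1m / (1 - p1m)) / (p0m / (1 - p0m))
    psi = draws.scalar("psi")
    if model.spec.clever_covariate:
        phi = draws.scalar("phi")
        eb = np.clip(ebar, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
        if model.spec.att_weighting:
            dh = 1.0 + eb / (1 - eb)
        else:
            dh = 1.0 / eb + 1.0 / (1 - eb)
        cond_or = np.exp(psi + phi * dh)
    else:
        cond_or = np.exp(psi)

    def central(v):
        return float(np.mean(v)), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))

    ate_pt, ate_lo, ate_hi = central(ates)
    or_pt, or_lo, or_hi = central(marg_or)
    cor_pt, cor_lo, cor_hi = central(cond_or)
    return {
        "risk-difference": EffectEstimate(
            "bayesian", "ATE", label, "risk-difference", ate_pt, ate_lo, ate_hi,
            n=S, extras={"posterior_sd": float(np.std(ates, ddof=1))},
        ),
        "odds-ratio": EffectEstimate(
            "bayesian", "ATE", label, "odds-ratio", or_pt, or_lo, or_hi,
            n=S,
            extras={
                "conditional_or": cor_pt,
                "conditional_or_lo": cor_lo,
                "conditional_or_hi": cor_hi,
            },
        ),
    }
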