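"""Compiled density kernel for the joint treatment/outcome model.

One fused pass computes the full log posterior density and its gradient
in the unconstrained parameterization. Layout offsets are passed as
integers (-1 when a component is absent) so a single compilation covers
every model configuration. The math mirrors the documented model in
``bayes``: non-centered regularized horseshoe coefficient blocks,
optional non-centered subgroup offsets for intercepts and coefficients,
and the clever-covariate coupling between the two Bernoulli likelihoods.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_EPS = 1e-6  # propensity clip for the clever covariate


@numba.njit(cache=True, fastmath=False)
def _decode_horseshoe(x, start, p, tau0, beta, lam, z):
    """Fill beta (and work arrays); return (tau, c2, logprior)."""
    for j in range(p):
        z[j] = x[start + j]
        lam[j] = math.exp(x[start + p + j])
    tau = math.exp(x[start + 2 * p])
    c2 = math.exp(x[start + 2 * p + 1])
    c = math.sqrt(c2)
    lp = 0.0
    for j in range(p):
        s = c2 + tau * tau * lam[j] * lam[j]
        m = tau * lam[j] * c / math.sqrt(s)
        beta[j] = z[j] * m
        lp += -0.5 * z[j] * z[j]
        lp += -math.log1p(lam[j] * lam[j]) + x[start + p + j]
    lp += -math.log1p((tau / tau0) ** 2) + x[start + 2 * p]
    return tau, c2, lp


@numba.njit(cache=True, fastmath=False)
def _grad_horseshoe(x, grad, start, p, tau0, a_ig, b_ig, g_beta):
    """Chain-rule the beta-gradient into (z, log lam, log tau, log c2)."""
    tau = math.exp(x[start + 2 * p])
    c2 = math.exp(x[start + 2 * p + 1])
    c = math.sqrt(c2)
    g_ltau = 0.0
    g_lw = 0.0
    for j in range(p):
        z = x[start + j]
        lam = math.exp(x[start + p + j])
        s = c2 + tau * tau * lam * lam
        s32 = s ** (-1.5)
        m = tau * lam * c / math.sqrt(s)
        grad[start + j] = g_beta[j] * m - z
        dm_dllam = lam * tau * c2 * c * s32
        grad[start + p + j] = g_beta[j] * z * dm_dllam - 2 * lam * lam / (1 + lam * lam) + 1.0
        g_ltau += g_beta[j] * z * (tau * lam * c2 * c * s32)
        g_lw += g_beta[j] * z * (0.5 * tau**3 * lam**3 * c * s32)
    grad[start + 2 * p] = g_ltau - 2 * (tau / tau0) ** 2 / (1 + (tau / tau0) ** 2) + 1.0
    grad[start + 2 * p + 1] = g_lw - a_ig + b_ig / c2


@numba.njit(cache=True, fastmath=False)
def joint_logp_grad(
    x, Xt, Xy, A, Y, gidx, G,
    use_h, att_form, fixed_H,
    tau0_t, tau0_y, a_ig, b_ig, s_int,
    it0, iths, itu0, itls0, itU, itlsU,
    iy0, iyhs, iyu0, iyls0, iyU, iylsU,
    ipsi, iphi,
):
    n = A.size
    pt = Xt.shape[1]
    py = Xy.shape[1]
    dim = x.size
    grad = np.zeros(dim)
    logp = 0.0

    # ---- decode natural parameters
    a0 = x[it0]
    g0 = x[iy0]
    beta_t = np.zeros(pt)
    beta_y = np.zeros(py)
    if pt > 0:
        zt = np.empty(pt)
        lamt = np.empty(pt)
        _, _, lp_hs = _decode_horseshoe(x, iths, pt, tau0_t, beta_t, lamt, zt)
        logp += lp_hs
    if py > 0:
        zy = np.empty(py)
        lamy = np.empty(py)
        _, _, lp_hs = _decode_horseshoe(x, iyhs, py, tau0_y, beta_y, lamy, zy)
        logp += lp_hs
    hier = itu0 >= 0
    coef_hier_t = itU >= 0 and pt > 0
    coef_hier_y = iyU >= 0 and py > 0
    sig0t = math.exp(x[itls0]) if hier else 0.0
    sig0y = math.exp(x[iyls0]) if hier else 0.0
    sigUt = math.exp(x[itlsU]) if coef_hier_t else 0.0
    sigUy = math.exp(x[iylsU]) if coef_hier_y else 0.0
    psi = x[ipsi]
    phi = x[iphi] if iphi >= 0 else 0.0

    # ---- likelihood pass with gradients w.r.t. linear predictors
    g_a0 = 0.0
    g_g0 = 0.0
    g_psi = 0.0
    g_phi = 0.0
    g_beta_t = np.zeros(pt)
    g_beta_y = np.zeros(py)
    gsum_t = np.zeros(G)
    gsum_y = np.zeros(G)
    Mt = np.zeros((G, pt))
    My = np.zeros((G, py))
    n_clip = 0
    for i in range(n):
        g = gidx[i]
        lt = a0
        for j in range(pt):
            coef = beta_t[j]
            if coef_hier_t:
                coef += sigUt * x[itU + g * pt + j]
            lt += Xt[i, j] * coef
        if hier:
            lt += sig0t * x[itu0 + g]
        ly = g0
        for j in range(py):
            coef = beta_y[j]
            if coef_hier_y:
                coef += sigUy * x[iyU + g * py + j]
            ly += Xy[i, j] * coef
        if hier:
            ly += sig0y * x[iyu0 + g]

        e = 1.0 / (1.0 + math.exp(-lt))
        sp = lt + math.log1p(math.exp(-lt)) if lt > 0 else math.log1p(math.exp(lt))
        logp += A[i] * lt - sp

        h = 0.0
        dh = 0.0
        if use_h:
            ec = e
            clipped = False
            if ec < _EPS:
                ec = _EPS
                clipped = True
                n_clip += 1
            elif ec > 1.0 - _EPS:
                ec = 1.0 - _EPS
                clipped = True
                n_clip += 1
            if fixed_H.size > 0:
                h = fixed_H[i]
            elif att_form:
                h = A[i] - (1.0 - A[i]) * ec / (1.0 - ec)
                dh = -(1.0 - A[i]) * ec / (1.0 - ec)
            else:
                h = A[i] / ec - (1.0 - A[i]) / (1.0 - ec)
                dh = -A[i] * (1.0 - ec) / ec - (1.0 - A[i]) * ec / (1.0 - ec)
            if clipped or fixed_H.size > 0:
                dh = 0.0
        ly += psi * A[i] + phi * h
        q = 1.0 / (1.0 + math.exp(-ly))
        sp = ly + math.log1p(math.exp(-ly)) if ly > 0 else math.log1p(math.exp(ly))
        logp += Y[i] * ly - sp
        r = Y[i] - q
        s = (A[i] - e) + r * phi * dh

        g_a0 += s
        g_g0 += r
        g_psi += r * A[i]
        g_phi += r * h
        for j in range(pt):
            v = s * Xt[i, j]
            g_beta_t[j] += v
            if coef_hier_t:
                Mt[g, j] += v
        for j in range(py):
            v = r * Xy[i, j]
            g_beta_y[j] += v
            if coef_hier_y:
                My[g, j] += v
        if hier:
            gsum_t[g] += s
            gsum_y[g] += r

    # ---- priors and parameter-space gradients
    logp += -0.5 * (a0 / s_int) ** 2 - 0.5 * (g0 / s_int) ** 2 - 0.5 * (psi / s_int) ** 2
    grad[it0] = g_a0 - a0 / s_int**2
    grad[iy0] = g_g0 - g0 / s_int**2
    grad[ipsi] = g_psi - psi / s_int**2
    if iphi >= 0:
        logp += -0.5 * (phi / s_int) ** 2
        grad[iphi] = g_phi - phi / s_int**2
    if pt > 0:
        logp += -a_ig * x[iths + 2 * pt + 1] - b_ig / math.exp(x[iths + 2 * pt + 1])
        _grad_horseshoe(x, grad, iths, pt, tau0_t, a_ig, b_ig, g_beta_t)
    if py > 0:
        logp += -a_ig * x[iyhs + 2 * py + 1] - b_ig / math.exp(x[iyhs + 2 * py + 1])
        _grad_horseshoe(x, grad, iyhs, py, tau0_y, a_ig, b_ig, g_beta_y)
    if hier:
        for which in range(2):
            iu0 = itu0 if which == 0 else iyu0
            ils0 = itls0 if which == 0 else iyls0
            sig0 = sig0t if which == 0 else sig0y
            gsum = gsum_t if which == 0 else gsum_y
            acc = 0.0
            for g in range(G):
                u = x[iu0 + g]
                grad[iu0 + g] = sig0 * gsum[g] - u
                acc += u * gsum[g]
                logp += -0.5 * u * u
            grad[ils0] = sig0 * acc - sig0 * sig0 + 1.0
            logp += -0.5 * sig0 * sig0 + math.log(sig0)
    if coef_hier_t or coef_hier_y:
        for which in range(2):
            if which == 0 and not coef_hier_t:
                continue
            if which == 1 and not coef_hier_y:
                continue
            iU = itU if which == 0 else iyU
            ilsU = itlsU if which == 0 else iylsU
            sigU = sigUt if which == 0 else sigUy
            M = Mt if which == 0 else My
            p = pt if which == 0 else py
            acc = 0.0
            for g in range(G):
                for j in range(p):
                    u = x[iU + g * p + j]
                    grad[iU + g * p + j] = sigU * M[g, j] - u
                    acc += u * M[g, j]
                    logp += -0.5 * u * u
            grad[ilsU] = sigU * acc - sigU * sigU + 1.0
            logp += -0.5 * sigU * sigU + math.log(sigU)

    return logp, grad, n_clip
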