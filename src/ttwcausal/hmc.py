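"""No-U-Turn Hamiltonian Monte Carlo with windowed warmup adaptation.

A self-contained NUTS implementation over a ``logp_and_grad`` callable:
slice-variant tree doubling with a divergence threshold of 1000 on the
Hamiltonian error, dual-averaging step-size adaptation toward a target
acceptance statistic, and diagonal mass-matrix estimation over expanding
warmup windows (initial buffer 75, doubling windows from 25, terminal
buffer 50, scaled proportionally for short warmups). Everything is driven
by a caller-supplied ``numpy.random.Generator``, so chains are exactly
reproducible from their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ChainResult", "run_nuts"]

_DELTA_MAX = 1000.0  # Hamiltonian-error divergence threshold


@dataclass
class ChainResult:
    positions: np.ndarray  # (n_draws, dim)
    logp: np.ndarray
    accept_stat: np.ndarray
    treedepth: np.ndarray
    divergent: np.ndarray  # bool per kept draw
    step_size: float
    inv_mass: np.ndarray

    @property
    def divergence_rate(self) -> float:
        return float(self.divergent.mean()) if len(self.divergent) else 0.0


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_initial_step(logp_grad, q, logp, grad, rng, inv_mass):
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    joint1 = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        joint1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * math.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "logp_prop", "g_prop", "n_valid", "keep_going", "alpha_sum", "n_alpha", "divergent",
    )


def _build_tree(logp_grad, q, p, grad, logu, v, depth, eps, joint0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, v * eps, inv_mass)
        joint = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(joint):
            joint = -np.inf
        divergent = (joint0 - joint) > _DELTA_MAX
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = grad1
        t.logp_prop = logp1
        t.n_valid = 1 if logu <= joint else 0
        t.keep_going = not divergent
        t.alpha_sum = min(1.0, math.exp(min(0.0, joint - joint0)))
        t.n_alpha = 1
        t.divergent = divergent
        return t
    first = _build_tree(logp_grad, q, p, grad, logu, v, depth - 1, eps, joint0, inv_mass, rng)
    t.q_minus, t.p_minus, t.g_minus = first.q_minus, first.p_minus, first.g_minus
    t.q_plus, t.p_plus, t.g_plus = first.q_plus, first.p_plus, first.g_plus
    t.q_prop, t.logp_prop, t.g_prop = first.q_prop, first.logp_prop, first.g_prop
    t.n_valid, t.keep_going = first.n_valid, first.keep_going
    t.alpha_sum, t.n_alpha, t.divergent = first.alpha_sum, first.n_alpha, first.divergent
    if not first.keep_going:
        return t
    if v == -1:
        second = _build_tree(
            logp_grad, first.q_minus, first.p_minus, first.g_minus,
            logu, v, depth - 1, eps, joint0, inv_mass, rng,
        )
        t.q_minus, t.p_minus, t.g_minus = second.q_minus, second.p_minus, second.g_minus
    else:
        second = _build_tree(
            logp_grad, first.q_plus, first.p_plus, first.g_plus,
            logu, v, depth - 1, eps, joint0, inv_mass, rng,
        )
        t.q_plus, t.p_plus, t.g_plus = second.q_plus, second.p_plus, second.g_plus
    total = first.n_valid + second.n_valid
    if second.n_valid > 0 and rng.random() < second.n_valid / total:
        t.q_prop, t.logp_prop, t.g_prop = second.q_prop, second.logp_prop, second.g_prop
    t.n_valid = total
    dq = t.q_plus - t.q_minus
    no_uturn = (np.dot(dq, inv_mass * t.p_minus) >= 0.0) and (np.dot(dq, inv_mass * t.p_plus) >= 0.0)
    t.keep_going = second.keep_going and no_uturn
    t.alpha_sum = first.alpha_sum + second.alpha_sum
    t.n_alpha = first.n_alpha + second.n_alpha
    t.divergent = first.divergent or second.divergent
    return t


def _adaptation_windows(n_warmup: int):
    """(init_buffer, mass-estimation window boundaries, start of term buffer)."""
    if n_warmup >= 150:
        init_buffer, term_buffer, base = 75, 50, 25
    else:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.10 * n_warmup))
        base = max(1, int(0.25 * n_warmup))
    term_start = n_warmup - term_buffer
    bounds = []
    start, width = init_buffer, base
    while start < term_start:
        end = start + width
        if end + 2 * width > term_start:
            end = term_start
        bounds.append(end)
        start, width = end, width * 2
    return init_buffer, bounds, term_start


def run_nuts(
    logp_and_grad,
    x0: np.ndarray,
    rng: np.random.Generator,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_mass0: np.ndarray | None = None,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and diagnostics."""
    q = np.asarray(x0, float).copy()
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial position has non-finite log density")
    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float).copy()

    eps = _find_initial_step(logp_and_grad, q, logp, grad, rng, inv_mass)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_buffer, window_bounds, term_start = _adaptation_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    n_total = n_warmup + n_draws
    positions = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accept_stats = np.empty(n_draws)
    depths = np.empty(n_draws, np.int64)
    divergents = np.zeros(n_draws, bool)

    for it in range(n_total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(p0, inv_mass)
        logu = joint0 + math.log(rng.random())
        q_minus = q_plus = q
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        q_prop, logp_prop, g_prop = q, logp, grad
        n_valid, keep_going, depth = 1, True, 0
        alpha_sum, n_alpha, divergent = 0.0, 0, False
        while keep_going and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(
                    logp_and_grad, q_minus, p_minus, g_minus, logu, v, depth, eps, joint0, inv_mass, rng
                )
                q_minus, p_minus, g_minus = t.q_minus, t.p_minus, t.g_minus
            else:
                t = _build_tree(
                    logp_and_grad, q_plus, p_plus, g_plus, logu, v, depth, eps, joint0, inv_mass, rng
                )
                q_plus, p_plus, g_plus = t.q_plus, t.p_plus, t.g_plus
            alpha_sum += t.alpha_sum
            n_alpha += t.n_alpha
            divergent = divergent or t.divergent
            if t.keep_going and t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
                q_prop, logp_prop, g_prop = t.q_prop, t.logp_prop, t.g_prop
            n_valid += t.n_valid
            dq = q_plus - q_minus
            keep_going = (
                t.keep_going
                and np.dot(dq, inv_mass * p_minus) >= 0.0
                and np.dot(dq, inv_mass * p_plus) >= 0.0
            )
            depth += 1
        q, logp, grad = q_prop, logp_prop, g_prop
        accept = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - accept) / (da_count + t0)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if init_buffer <= it < term_start:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
                if (it + 1) in window_bounds:
                    var = welford_m2 / max(welford_n - 1, 1)
                    # Stan-style shrinkage toward unit metric
                    var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (5.0 / (welford_n + 5.0))
                    inv_mass = np.maximum(var, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    eps = _find_initial_step(logp_and_grad, q, logp, grad, rng, inv_mass)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            k = it - n_warmup
            positions[k] = q
            logps[k] = logp
            accept_stats[k] = accept
            depths[k] = depth
            divergents[k] = divergent

    return ChainResult(
        positions=positions,
        logp=logps,
        accept_stat=accept_stats,
        treedepth=depths,
        divergent=divergents,
        step_size=eps,
        inv_mass=inv_mass,
    )
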