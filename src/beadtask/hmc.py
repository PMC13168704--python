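"""A compact Hamiltonian Monte Carlo sampler.

Gradient-based MCMC for the hierarchical stopping models: static-
trajectory HMC with dual-averaging step-size adaptation (target
acceptance 0.8), a diagonal mass matrix estimated during a middle
warm-up window, and jittered leapfrog path lengths to avoid resonance.
Transitions whose energy error exceeds a large threshold are counted as
divergent and rejected.

The interface is a single function taking ``logp_and_grad`` so that any
differentiable log-density can be sampled; the fitting layer supplies
the non-centered hierarchical posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float
    n_leapfrog: int


def _find_initial_step(logp_and_grad, x, inv_mass, rng, eps0=None):
    """Stan-style heuristic: double/halve eps until P(accept) crosses 0.5."""
    dim = len(x)
    eps = eps0 if eps0 is not None else 0.1 * dim ** -0.25
    lp, grad = logp_and_grad(x)
    p = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -lp + 0.5 * np.sum(p * p * inv_mass)

    def energy_after(eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * p1 * inv_mass
        lp1, g1 = logp_and_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return -lp1 + 0.5 * np.sum(p1 * p1 * inv_mass)

    try:
        delta = h0 - energy_after(eps)
    except FloatingPointError:
        delta = -np.inf
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(50):
        try:
            delta = h0 - energy_after(eps)
        except FloatingPointError:
            delta = -np.inf
        if direction == 1 and not delta > np.log(0.5):
            break
        if direction == -1 and not delta < np.log(0.5):
            break
        eps *= 2.0 ** direction
    return float(np.clip(eps, 1e-6, 10.0))


def sample_chain(
    logp_and_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    trajectory_length: float = 1.0,
    max_leapfrog: int = 48,
) -> ChainResult:
    """Run one HMC chain and return post-warmup draws."""
    x = np.array(x0, dtype=float)
    dim = len(x)
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_and_grad, x, inv_mass, rng)

    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-adaptation window (Welford) over the middle of warm-up
    w_lo, w_hi = int(0.25 * n_warmup), int(0.8 * n_warmup)
    mean_acc = np.zeros(dim)
    m2_acc = np.zeros(dim)
    n_acc = 0

    lp, grad = logp_and_grad(x)
    da_start = 0
    draws = np.empty((n_draws, dim))
    n_accept, n_div = 0.0, 0
    total = n_warmup + n_draws
    leapfrogs_used = 0

    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(p0 * p0 * inv_mass)
        n_leap = max(1, int(np.ceil(trajectory_length / eps)))
        n_leap = min(n_leap, max_leapfrog)
        n_leap = int(rng.integers(max(1, n_leap // 2), n_leap + 1))
        leapfrogs_used = n_leap

        xn, pn, gn, lpn = x, p0, grad, lp
        diverged = False
        try:
            with np.errstate(over="raise", invalid="raise"):
                pn = pn + 0.5 * eps * gn
                for step in range(n_leap):
                    xn = xn + eps * pn * inv_mass
                    lpn, gn = logp_and_grad(xn)
                    if not np.all(np.isfinite(gn)) or not np.isfinite(lpn):
                        raise FloatingPointError
                    if step < n_leap - 1:
                        pn = pn + eps * gn
                pn = pn + 0.5 * eps * gn
        except FloatingPointError:
            diverged = True

        if not diverged:
            h1 = -lpn + 0.5 * np.sum(pn * pn * inv_mass)
            delta = h0 - h1
            if not np.isfinite(delta) or -delta > DIVERGENCE_THRESHOLD:
                diverged = True
        if diverged:
            accept_prob = 0.0
            if not warming:
                n_div += 1
        else:
            accept_prob = min(1.0, np.exp(min(delta, 0.0)))
            if rng.random() < accept_prob:
                x, lp, grad = xn, lpn, gn

        if warming:
            # dual averaging
            m = it - da_start + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu_da - np.sqrt(m) / gamma * h_bar
            w = m ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_lo <= it < w_hi:
                n_acc += 1
                d = x - mean_acc
                mean_acc += d / n_acc
                m2_acc += d * (x - mean_acc)
            if it == w_hi - 1 and n_acc > 10:
                var = m2_acc / (n_acc - 1)
                inv_mass = np.clip(var, 1e-8, 1e8)
                # restart step-size adaptation for the new metric
                eps = _find_initial_step(logp_and_grad, x, inv_mass, rng, eps)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                da_start = it + 1
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0.0 else eps
        else:
            n_accept += accept_prob
            draws[it - n_warmup] = x

    return ChainResult(draws, n_accept / max(1, n_draws), n_div, eps, leapfrogs_used)
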