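"""Gradient-based MCMC machinery shared by both models.

An adaptive Hamiltonian Monte Carlo sampler operating on an unconstrained
parameter vector: leapfrog integration with a uniformly jittered path
length, dual-averaging step-size adaptation towards a target acceptance
statistic, and a single diagonal mass-matrix estimation window during
warm-up.  Models supply ``logp_and_grad(q) -> (float, ndarray)`` with
hand-derived analytic gradients.

Also provides the unconstrained parameterisation of a correlation-matrix
Cholesky factor via canonical partial correlations (the tanh transform), with
the log-density terms that make an LKJ prior on the correlation correct on
the unconstrained scale, and the matching backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "HMCResult",
    "sample_hmc",
    "chol_corr_forward",
    "chol_corr_backward",
    "lkj_chol_logprior_unconstrained",
    "lkj_chol_logprior_grad",
    "numerical_gradient",
]


@dataclass
class HMCResult:
    """Raw draws from one or more HMC chains on the unconstrained scale."""

    positions: np.ndarray  # (chains, draws, dim)
    divergences: int
    accept_rate: float
    step_sizes: np.ndarray  # (chains,)
    inv_mass: np.ndarray  # (chains, dim)


def _find_reasonable_step(logp_grad, q, rng, inv_mass):
    """Coarse bracketing of the step size before dual averaging starts."""
    eps = 0.1
    lp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p * p)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, eps, 1, inv_mass, grad)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(h1):
        return 1e-3
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(30):
        eps *= 2.0**direction
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, eps, 1, inv_mass, grad)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-6)


def _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass, grad):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.all(np.isfinite(grad)) or not np.isfinite(lp):
            return q, p, -np.inf, grad
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return q, p, lp, grad


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
) -> HMCResult:
    """Run adaptive HMC chains and return post-warm-up positions.

    The path length for each transition is drawn uniformly from
    ``{1, ..., max_leapfrog}`` leapfrog steps, which avoids resonant
    trajectories without tree building.  Divergent transitions (energy error
    beyond 1000 or a non-finite state) are rejected and counted only after
    warm-up.
    """
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    all_pos, all_eps, all_imass = [], [], []
    divergences = 0
    n_accept = 0
    n_total = 0

    for c in range(n_chains):
        rng = np.random.default_rng(seqs[c])
        q = np.array(init(rng) if callable(init) else init, dtype=float)
        dim = q.size
        inv_mass = np.ones(dim)
        eps = _find_reasonable_step(logp_grad, q, rng, inv_mass)

        # dual averaging state
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        adapt_iter = 0

        # single mass window inside warm-up
        w_lo, w_hi = int(0.15 * n_warmup), int(0.80 * n_warmup)
        welford_n, welford_mean = 0, np.zeros(dim)
        welford_m2 = np.zeros(dim)

        lp, grad = logp_grad(q)
        draws = np.empty((n_draws, dim))
        for it in range(n_warmup + n_draws):
            warm = it < n_warmup
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = lp - 0.5 * np.sum(inv_mass * p * p)
            L = int(rng.integers(1, max_leapfrog + 1))
            q1, p1, lp1, grad1 = _leapfrog(
                logp_grad, q, p, eps, L, inv_mass, grad
            )
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
            delta_h = h1 - h0
            diverged = (not np.isfinite(delta_h)) or (delta_h < -1000.0)
            alpha = 0.0 if diverged else min(1.0, float(np.exp(min(delta_h, 0.0))))
            if not warm:
                n_total += 1
                if diverged:
                    divergences += 1
            if (not diverged) and rng.uniform() < alpha:
                q, lp, grad = q1, lp1, grad1
                if not warm:
                    n_accept += 1

            if warm:
                adapt_iter += 1
                frac = 1.0 / (adapt_iter + t0)
                h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
                log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
                w = adapt_iter ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if w_lo <= it < w_hi:
                    welford_n += 1
                    d = q - welford_mean
                    welford_mean += d / welford_n
                    welford_m2 += d * (q - welford_mean)
                if it == w_hi - 1 and welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    # regularise towards unit scale, as adaptation windows do
                    var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                    inv_mass = np.maximum(var, 1e-8)
                    eps = float(np.exp(log_eps_bar))
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
                if it == n_warmup - 1:
                    eps = float(np.exp(log_eps_bar)) if adapt_iter else eps
            else:
                draws[it - n_warmup] = q

        all_pos.append(draws)
        all_eps.append(eps)
        all_imass.append(inv_mass)

    return HMCResult(
        positions=np.stack(all_pos),
        divergences=divergences,
        accept_rate=n_accept / max(n_total, 1),
        step_sizes=np.array(all_eps),
        inv_mass=np.stack(all_imass),
    )


# ---------------------------------------------------------------------------
# Correlation Cholesky transform (canonical partial correlations)
# ---------------------------------------------------------------------------
#
# A correlation matrix R = L L' with unit-diagonal rows is parameterised by
# the strictly-lower-triangular canonical partial correlations
# z_ij = tanh(x_ij).  Writing w_ij = sqrt(1 - z_ij^2), the factor has the
# closed form
#
#     L_ij = z_ij * prod_{k<j} w_ik   (j < i),     L_ii = prod_{k<i} w_ik,
#
# which makes both the forward map and its adjoint straightforward.


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def n_corr_params(n: int) -> int:
    return n * (n - 1) // 2


def chol_corr_forward(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained vector -> (L, z) with L the correlation Cholesky factor."""
    rows, cols = _tri_indices(n)
    if x.size != rows.size:
        raise ValueError(f"expected {rows.size} parameters for n={n}")
    z = np.zeros((n, n))
    z[rows, cols] = np.tanh(x)
    L = np.zeros((n, n))
    L[0, 0] = 1.0
    for i in range(1, n):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[i, j] * np.sqrt(rem)
            rem *= 1.0 - z[i, j] ** 2
        L[i, i] = np.sqrt(rem)
    return L, z


def chol_corr_backward(
    dL: np.ndarray, L: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Adjoint of :func:`chol_corr_forward`.

    Given the gradient of a scalar objective with respect to every entry of
    L (including the diagonal), returns its gradient with respect to the
    unconstrained vector x.
    """
    n = L.shape[0]
    rows, cols = _tri_indices(n)
    dx = np.zeros(rows.size)
    pos = {(i, j): t for t, (i, j) in enumerate(zip(rows, cols))}
    for i in range(1, n):
        for k in range(i):
            zik = z[i, k]
            one_m = 1.0 - zik**2
            # direct term: dL_ik / dz_ik = L_ik / z_ik = prod_{j<k} w_ij
            if abs(zik) > 1e-12:
                direct = dL[i, k] * (L[i, k] / zik)
            else:
                prod_w = 1.0
                for j in range(k):
                    prod_w *= np.sqrt(1.0 - z[i, j] ** 2)
                direct = dL[i, k] * prod_w
            # downstream terms: every L_ib with b > k (incl. diagonal) scales
            # with w_ik, so d ln L_ib / d z_ik = -z_ik / (1 - z_ik^2)
            downstream = 0.0
            for b in range(k + 1, i + 1):
                downstream += dL[i, b] * L[i, b]
            dz = direct - (zik / one_m) * downstream
            dx[pos[(i, k)]] = dz * one_m  # z = tanh(x)
    return dx


def lkj_chol_logprior_unconstrained(
    x: np.ndarray, n: int, eta: float = 1.0
) -> float:
    """Log density on x of an LKJ(eta) correlation prior, Jacobian included.

    The LKJ Cholesky density prod_i L_ii^(n-i+2*eta-2) combined with the
    log-Jacobian of the tanh / partial-correlation transform collapses to
    sum over columns k of [(n-k)/2 + eta - 1] * log(1 - z^2) per element
    (0-indexed column k), so no L needs to be built.
    """
    rows, cols = _tri_indices(n)
    z = np.tanh(x)
    alpha = (n - cols) / 2.0 + eta - 1.0
    with np.errstate(divide="ignore"):
        return float(np.sum(alpha * np.log1p(-(z**2))))


def lkj_chol_logprior_grad(
    x: np.ndarray, n: int, eta: float = 1.0
) -> np.ndarray:
    rows, cols = _tri_indices(n)
    z = np.tanh(x)
    alpha = (n - cols) / 2.0 + eta - 1.0
    return -2.0 * alpha * z


def numerical_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Central finite differences; the oracle against analytic gradients."""
    g = np.zeros_like(x, dtype=float)
    for i in range(x.size):
        d = np.zeros_like(x, dtype=float)
        d[i] = eps
        g[i] = (f(x + d) - f(x - d)) / (2 * eps)
    return g
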