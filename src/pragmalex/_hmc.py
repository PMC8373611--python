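"""Preconditioned static Hamiltonian Monte Carlo with batched chains.

Chains run in lock-step so that every leapfrog step needs exactly one batched
log-posterior-and-gradient evaluation for all chains. The caller supplies the
target in *whitened* coordinates (centred at the posterior mode, scaled by a
Cholesky factor of the Laplace covariance); warmup then adapts

* the step size by dual averaging toward a target acceptance rate, and
* a diagonal mass matrix from the warmup draws (second window), which mops
  up whatever scale structure the Laplace preconditioner missed.

The number of leapfrog steps is jittered per iteration to avoid resonances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["HMCResult", "hmc_sample"]


@dataclass
class HMCResult:
    draws: np.ndarray  # (chains, draws, dim)
    accept_rate: float
    step_size: float
    divergences: int


class _DualAveraging:
    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.m = 0
        self.target = target
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75
        self.eps = eps0

    def update(self, accept_mean: float) -> None:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_mean)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1.0 - w) * self.log_eps_bar
        self.eps = float(np.exp(log_eps))

    def finalize(self) -> float:
        self.eps = float(np.exp(self.log_eps_bar))
        return self.eps


def hmc_sample(
    logp_and_grad: Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    n_leapfrog: int = 16,
    target_accept: float = 0.8,
    init_step: float = 0.2,
) -> HMCResult:
    """Sample with static HMC; ``x0`` is ``(chains, dim)`` in whitened coords."""
    x = np.array(x0, dtype=float)
    n_chains, ndim = x.shape
    lp, grad = logp_and_grad(x)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial states have non-finite log posterior")

    scale = np.ones(ndim)  # sqrt of the inverse mass, adapted mid-warmup
    da = _DualAveraging(float(init_step), target_accept)
    draws = np.empty((n_chains, n_draws, ndim))
    collect_from = max(5, n_warmup // 4)
    collect_to = max(collect_from + 5, (3 * n_warmup) // 4)
    warm_buf = np.empty((n_chains, collect_to - collect_from, ndim))
    n_accept = 0
    n_total = 0
    divergences = 0
    lo = max(2, int(np.floor(0.75 * n_leapfrog)))
    hi = max(lo + 1, int(np.ceil(1.25 * n_leapfrog)) + 1)

    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_warmup + n_draws):
            eps = da.eps
            n_steps = int(rng.integers(lo, hi))
            p0 = rng.standard_normal((n_chains, ndim))
            xn = x.copy()
            pn = p0 + 0.5 * eps * scale * grad
            bad = np.zeros(n_chains, dtype=bool)
            gn = grad
            for step in range(n_steps):
                xn = xn + eps * scale * pn
                lpn, gn = logp_and_grad(xn)
                bad |= ~np.isfinite(lpn)
                gn = np.where(np.isfinite(gn), gn, 0.0)
                if step < n_steps - 1:
                    pn = pn + eps * scale * gn
            pn = pn + 0.5 * eps * scale * gn

            h0 = -lp + 0.5 * np.sum(p0**2, axis=1)
            h1 = np.where(bad, np.inf, -lpn + 0.5 * np.sum(pn**2, axis=1))
            delta = h0 - h1
            delta = np.where(np.isnan(delta), -np.inf, delta)
            divergences += int(np.sum(delta < -1000.0))
            acc_prob = np.exp(np.minimum(0.0, delta))
            accept = rng.random(n_chains) < acc_prob
            if np.any(accept):
                x[accept] = xn[accept]
                lp[accept] = lpn[accept]
                grad[accept] = gn[accept]

            if t < n_warmup:
                da.update(float(np.mean(acc_prob)))
                if collect_from <= t < collect_to:
                    warm_buf[:, t - collect_from] = x
                if t == collect_to - 1:
                    sd = warm_buf.reshape(-1, ndim).std(axis=0)
                    # conservative clip: correct scales, never explode them
                    scale = np.clip(sd, 0.2, 5.0)
                    # restart step-size adaptation under the new metric
                    da = _DualAveraging(max(da.finalize(), 1e-3), target_accept)
                if t == n_warmup - 1:
                    da.finalize()
            else:
                draws[:, t - n_warmup] = x
                n_accept += int(np.sum(accept))
                n_total += n_chains

    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(n_total, 1),
        step_size=da.eps,
        divergences=divergences,
    )
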