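"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass adaptation.

A compact NUTS-free sampler adequate for the package's hierarchical logistic
posteriors: the models expose cheap analytic gradients, the hierarchy is
non-centered (so the geometry is mild), and trajectory lengths are jittered
to avoid resonance. Chains run in lockstep as a vectorized batch.

Warmup follows the usual three-phase schedule: a fast initial buffer that
adapts only the step size, a sequence of doubling "memoryless" windows that
each re-estimate the diagonal mass matrix from the window's own samples
(and restart step-size adaptation), and a final buffer that settles the step
size against the last mass matrix.

The target density callback receives ``theta`` of shape ``(chains, dim)``
and returns ``(logp (chains,), grad (chains, dim))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample"]


@dataclass
class HMCResult:
    draws: np.ndarray          # (chains, n_draws, dim)
    accept_rate: np.ndarray    # (chains,)
    step_size: np.ndarray      # (chains,)
    mass_diag: np.ndarray      # (dim,)
    divergences: int


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0, target):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = np.zeros_like(eps0)
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob):
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    def restart(self):
        self.mu = np.log(10.0) + self.log_eps_bar
        self.log_eps = self.log_eps_bar.copy()
        self.h_bar = np.zeros_like(self.h_bar)
        self.t = 0

    @property
    def eps(self):
        return np.exp(self.log_eps)

    @property
    def eps_final(self):
        return np.exp(self.log_eps_bar)


def _warmup_windows(n_warmup):
    """(start, end, is_mass_window) phases: fast buffer, doubling windows, settle."""
    init = max(20, int(0.1 * n_warmup))
    term = max(20, int(0.1 * n_warmup))
    phases = [(0, init, False)]
    pos, size = init, max(25, int(0.08 * n_warmup))
    while pos < n_warmup - term:
        end = min(pos + size, n_warmup - term)
        # absorb a too-small trailing window into the last one
        if n_warmup - term - end < 25:
            end = n_warmup - term
        phases.append((pos, end, True))
        pos, size = end, size * 2
    phases.append((n_warmup - term, n_warmup, False))
    return phases


def _leapfrog(logp_grad, theta, p, eps, n_steps, inv_mass):
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps[:, None] * grad
    for _ in range(n_steps):
        theta = theta + eps[:, None] * (inv_mass[None, :] * p)
        logp, grad = logp_grad(theta)
        p = p + eps[:, None] * grad
    p = p - 0.5 * eps[:, None] * grad
    return theta, p, logp


def sample(
    logp_grad: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.9,
    base_steps: int = 16,
    max_step_jitter: int = 8,
) -> HMCResult:
    """Run vectorized HMC chains from initial states ``theta0 (chains, dim)``.

    Energy errors above 1000 count as divergences (the proposal is rejected);
    they are reported only for post-warmup iterations.
    """
    theta = np.array(theta0, dtype=float)
    n_chains, dim = theta.shape
    mass = np.ones(dim)
    inv_mass = 1.0 / mass
    da = _DualAveraging(np.full(n_chains, 0.05), target_accept)

    phases = _warmup_windows(n_warmup)
    phase_idx = 0
    window_samples: list[np.ndarray] = []

    draws = np.empty((n_chains, n_draws, dim))
    n_accept = np.zeros(n_chains)
    divergences = 0
    eps = da.eps

    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        n_steps = base_steps + int(rng.integers(0, max_step_jitter + 1))
        p0 = rng.standard_normal((n_chains, dim)) * np.sqrt(mass)[None, :]
        logp0, _ = logp_grad(theta)
        ham0 = -logp0 + 0.5 * np.einsum("cd,d,cd->c", p0, inv_mass, p0)
        theta_new, p_new, logp_new = _leapfrog(
            logp_grad, theta, p0, eps, n_steps, inv_mass
        )
        ham1 = -logp_new + 0.5 * np.einsum("cd,d,cd->c", p_new, inv_mass, p_new)
        d_energy = ham0 - ham1
        d_energy = np.where(np.isnan(d_energy), -np.inf, d_energy)
        divergent = d_energy < -1000.0
        divergences += int(np.sum(divergent & ~warm))
        accept_prob = np.where(
            divergent, 0.0, np.minimum(1.0, np.exp(np.minimum(d_energy, 0.0)))
        )
        accepted = rng.random(n_chains) < accept_prob
        theta = np.where(accepted[:, None], theta_new, theta)

        if warm:
            da.update(accept_prob)
            eps = da.eps
            start, end, is_mass = phases[phase_idx]
            if is_mass:
                window_samples.append(theta.copy())
            if it == end - 1:
                if is_mass and len(window_samples) >= 10:
                    samp = np.concatenate(window_samples, axis=0)
                    var = samp.var(axis=0)
                    mass = 1.0 / np.maximum(var, 1e-10)
                    inv_mass = var
                    da.restart()
                    eps = da.eps
                window_samples = []
                phase_idx = min(phase_idx + 1, len(phases) - 1)
            if it == n_warmup - 1:
                # slightly conservative final step size: trims the rare
                # integrator blow-ups the dual-averaged value admits
                eps = 0.8 * da.eps_final
        else:
            draws[:, it - n_warmup, :] = theta
            n_accept += accepted

    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        mass_diag=mass,
        divergences=divergences,
    )
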