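"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained NUTS-class Hamiltonian Monte Carlo implementation
operating on an arbitrary differentiable log density: binary doubling of
the leapfrog trajectory with slice sampling of the candidate state, the
standard u-turn termination criterion, dual averaging of the step size
toward a target acceptance statistic during warmup, and a diagonal mass
matrix estimated from the middle of the warmup phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_DELTA = 1000.0  # energy error treated as divergence


@dataclass
class SamplerStats:
    step_size: float
    inv_mass: np.ndarray
    divergences: int
    mean_accept: float
    mean_treedepth: float


def _leapfrog(theta, r, grad, eps, logp_grad, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _kinetic(r, inv_mass) -> float:
    return 0.5 * float(np.dot(r, inv_mass * r))


def find_reasonable_epsilon(logp_grad: LogpGrad, theta: np.ndarray, rng, inv_mass) -> float:
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 0.5."""
    eps = 1.0
    logp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, logp_grad, inv_mass)
    joint1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, logp_grad, inv_mass)
        joint1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


def _build_tree(theta, r, grad, logu, v, depth, eps, joint0, logp_grad, inv_mass, rng):
    """Recursive trajectory doubling; returns the subtree summary."""
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(theta, r, grad, v * eps, logp_grad, inv_mass)
        joint = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(joint):
            joint = -np.inf
        n_valid = int(logu <= joint)
        no_divergence = logu - _MAX_DELTA < joint
        alpha = min(1.0, np.exp(min(joint - joint0, 0.0)))
        return (
            theta1, r1, grad1, theta1, r1, grad1,
            theta1, grad1, logp1, n_valid, no_divergence, alpha, 1,
            not no_divergence,
        )
    (
        tm, rm, gm, tp, rp, gp, tprop, gprop, lprop, n1, s1, a1, na1, div1,
    ) = _build_tree(theta, r, grad, logu, v, depth - 1, eps, joint0, logp_grad, inv_mass, rng)
    if s1:
        if v == -1:
            (tm, rm, gm, _, _, _, tprop2, gprop2, lprop2, n2, s2, a2, na2, div2) = _build_tree(
                tm, rm, gm, logu, v, depth - 1, eps, joint0, logp_grad, inv_mass, rng
            )
        else:
            (_, _, _, tp, rp, gp, tprop2, gprop2, lprop2, n2, s2, a2, na2, div2) = _build_tree(
                tp, rp, gp, logu, v, depth - 1, eps, joint0, logp_grad, inv_mass, rng
            )
        if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
            tprop, gprop, lprop = tprop2, gprop2, lprop2
        dtheta = tp - tm
        s1 = (
            s2
            and (np.dot(dtheta, inv_mass * rm) >= 0)
            and (np.dot(dtheta, inv_mass * rp) >= 0)
        )
        n1 += n2
        a1 += a2
        na1 += na2
        div1 = div1 or div2
    return tm, rm, gm, tp, rp, gp, tprop, gprop, lprop, n1, s1, a1, na1, div1


def nuts_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_mass0: np.ndarray | None = None,
) -> tuple[np.ndarray, SamplerStats]:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics.

    ``inv_mass0`` seeds the diagonal inverse mass matrix with rough
    per-parameter posterior variances (refined during warmup); a good hint
    avoids the deep trajectories of the badly conditioned early phase.
    """
    theta = np.asarray(x0, dtype=float).copy()
    dim = theta.size
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, dtype=float).copy()

    # dual-averaging state
    eps = find_reasonable_epsilon(logp_grad, theta, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    # expanding mass-adaptation windows between an initial fast buffer and a
    # terminal step-size-only buffer
    init_buffer = min(75, max(20, n_warmup // 4))
    term_buffer = min(50, max(10, n_warmup // 5))
    base_window = 25
    window_ends: list[int] = []
    if n_warmup >= init_buffer + term_buffer + base_window:
        pos, width = init_buffer, base_window
        while pos + width < n_warmup - term_buffer:
            # final window absorbs the remainder
            if pos + 3 * width >= n_warmup - term_buffer:
                width = n_warmup - term_buffer - pos
            window_ends.append(pos + width)
            pos += width
            width *= 2
    window_draws: list[np.ndarray] = []

    samples = np.empty((n_samples, dim))
    divergences = 0
    accept_sum, accept_n, depth_sum = 0.0, 0, 0

    for it in range(n_warmup + n_samples):
        warming = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(r0, inv_mass)
        logu = joint0 + np.log(rng.uniform())
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        prop_theta, prop_grad, prop_logp = theta, grad, logp
        n_valid, keep_going = 1, True
        alpha_sum, n_alpha = 0.0, 0
        depth = 0
        while keep_going and depth < max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                (tm, rm, gm, _, _, _, tprop, gprop, lprop, n1, s1, a1, na1, div) = _build_tree(
                    tm, rm, gm, logu, v, depth, eps, joint0, logp_grad, inv_mass, rng
                )
            else:
                (_, _, _, tp, rp, gp, tprop, gprop, lprop, n1, s1, a1, na1, div) = _build_tree(
                    tp, rp, gp, logu, v, depth, eps, joint0, logp_grad, inv_mass, rng
                )
            if div:
                divergences += 1
            if s1 and rng.uniform() < min(1.0, n1 / max(n_valid, 1)):
                prop_theta, prop_grad, prop_logp = tprop, gprop, lprop
            n_valid += n1
            alpha_sum += a1
            n_alpha += na1
            dtheta = tp - tm
            keep_going = (
                s1
                and (np.dot(dtheta, inv_mass * rm) >= 0)
                and (np.dot(dtheta, inv_mass * rp) >= 0)
            )
            depth += 1
        theta, grad, logp = prop_theta, prop_grad, prop_logp
        accept_stat = alpha_sum / max(n_alpha, 1)

        if warming:
            da_iter += 1
            eta = 1.0 / (da_iter + t0)
            h_bar = (1.0 - eta) * h_bar + eta * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_ends and it >= init_buffer:
                window_draws.append(theta.copy())
            if window_ends and it + 1 == window_ends[0]:
                window_ends.pop(0)
                if len(window_draws) >= 10:
                    var = np.var(np.asarray(window_draws), axis=0)
                    n_w = len(window_draws)
                    inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    inv_mass = np.clip(inv_mass, 1e-8, None)
                    eps = find_reasonable_epsilon(logp_grad, theta, rng, inv_mass)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
                window_draws = []
        else:
            if it == n_warmup and n_warmup > 0:
                eps = float(np.exp(log_eps_bar))
            samples[it - n_warmup] = theta
            accept_sum += accept_stat
            accept_n += 1
            depth_sum += depth

    stats = SamplerStats(
        step_size=eps,
        inv_mass=inv_mass,
        divergences=divergences,
        mean_accept=accept_sum / max(accept_n, 1),
        mean_treedepth=depth_sum / max(accept_n, 1),
    )
    return samples, stats
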