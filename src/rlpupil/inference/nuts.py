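"""A compact No-U-Turn sampler with dual-averaging step-size adaptation and
diagonal mass-matrix estimation during warmup.

The sampler is deliberately backend-agnostic: it needs only a callable
``logp_grad(theta) -> (float, ndarray)`` over an unconstrained parameter
vector, so the model contract (joint log-density + gradient) is the whole
interface.  The implementation follows the slice-sampling formulation of
the algorithm with multiplicative termination checks, a maximum tree depth
of 10 and a divergence threshold of 1000 nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplerConfig", "NutsStats", "nuts_sample"]

_MAX_DEPTH = 10
_DIVERGENCE = 1000.0


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    iterations: int = 2000  # total per chain, warmup included
    warmup: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = _MAX_DEPTH

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class NutsStats:
    divergences: int = 0
    max_treedepth_hits: int = 0
    step_size: float = float("nan")
    accept_mean: float = float("nan")
    extra: dict = field(default_factory=dict)


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "n_valid", "keep_going", "alpha", "n_alpha", "diverged",
    )


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * inv_mass * r_half
    logp_new, grad_new = logp_grad(theta_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, logp_new, grad_new


def _kinetic(r, inv_mass):
    return 0.5 * float(r @ (inv_mass * r))


def _find_initial_step(logp_grad, theta, rng, inv_mass):
    eps = 1.0
    logp, grad = logp_grad(theta)
    r = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, theta, r, grad, log_u, v, depth, eps, h0, inv_mass, rng):
    out = _Tree()
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        out.n_valid = 1 if log_u <= h1 else 0
        out.diverged = log_u - _DIVERGENCE > h1
        out.keep_going = not out.diverged
        out.theta_minus = out.theta_plus = theta1
        out.r_minus = out.r_plus = r1
        out.grad_minus = out.grad_plus = grad1
        out.theta_prop = theta1
        out.alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        out.n_alpha = 1
        return out

    first = _build_tree(logp_grad, theta, r, grad, log_u, v, depth - 1, eps, h0, inv_mass, rng)
    out.theta_minus, out.r_minus, out.grad_minus = first.theta_minus, first.r_minus, first.grad_minus
    out.theta_plus, out.r_plus, out.grad_plus = first.theta_plus, first.r_plus, first.grad_plus
    out.theta_prop = first.theta_prop
    out.n_valid = first.n_valid
    out.alpha = first.alpha
    out.n_alpha = first.n_alpha
    out.diverged = first.diverged
    out.keep_going = first.keep_going
    if not first.keep_going:
        return out

    if v == -1:
        second = _build_tree(
            logp_grad, first.theta_minus, first.r_minus, first.grad_minus,
            log_u, v, depth - 1, eps, h0, inv_mass, rng,
        )
        out.theta_minus, out.r_minus, out.grad_minus = (
            second.theta_minus, second.r_minus, second.grad_minus,
        )
    else:
        second = _build_tree(
            logp_grad, first.theta_plus, first.r_plus, first.grad_plus,
            log_u, v, depth - 1, eps, h0, inv_mass, rng,
        )
        out.theta_plus, out.r_plus, out.grad_plus = (
            second.theta_plus, second.r_plus, second.grad_plus,
        )
    total = first.n_valid + second.n_valid
    if second.n_valid > 0 and rng.random() < second.n_valid / max(total, 1):
        out.theta_prop = second.theta_prop
    out.n_valid = total
    out.alpha = first.alpha + second.alpha
    out.n_alpha = first.n_alpha + second.n_alpha
    out.diverged = first.diverged or second.diverged
    dtheta = out.theta_plus - out.theta_minus
    no_uturn = (
        float(dtheta @ (inv_mass * out.r_minus)) >= 0
        and float(dtheta @ (inv_mass * out.r_plus)) >= 0
    )
    out.keep_going = second.keep_going and (not out.diverged) and no_uturn
    return out


def _nuts_chain(logp_grad, theta0, n_iter, n_warmup, rng, target_accept, max_treedepth):
    dim = len(theta0)
    inv_mass = np.ones(dim)
    theta = np.asarray(theta0, dtype=float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise RuntimeError("initialisation failed: non-finite log density at start")

    eps = _find_initial_step(logp_grad, theta, rng, inv_mass)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # warmup windows for mass-matrix updates (fractions of warmup)
    checkpoints = sorted({int(n_warmup * f) for f in (0.4, 0.7, 0.9) if n_warmup >= 20})
    window: list[np.ndarray] = []

    draws = np.empty((n_iter - n_warmup, dim))
    stats = NutsStats(extra={"treedepth": []})
    accept_sum, accept_n = 0.0, 0

    for it in range(n_iter):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(r0, inv_mass)
        log_u = h0 + np.log(rng.random())
        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_prop = theta
        n_valid = 1
        depth = 0
        keep_going = True
        alpha_stat, n_alpha = 0.0, 1
        while keep_going and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                tree = _build_tree(
                    logp_grad, theta_minus, r_minus, grad_minus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                theta_minus, r_minus, grad_minus = tree.theta_minus, tree.r_minus, tree.grad_minus
            else:
                tree = _build_tree(
                    logp_grad, theta_plus, r_plus, grad_plus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                theta_plus, r_plus, grad_plus = tree.theta_plus, tree.r_plus, tree.grad_plus
            if tree.diverged:
                stats.divergences += 1
            if tree.keep_going and tree.n_valid > 0:
                if rng.random() < min(1.0, tree.n_valid / n_valid):
                    theta_prop = tree.theta_prop
            n_valid += tree.n_valid
            alpha_stat, n_alpha = tree.alpha, tree.n_alpha
            dtheta = theta_plus - theta_minus
            keep_going = (
                tree.keep_going
                and float(dtheta @ (inv_mass * r_minus)) >= 0
                and float(dtheta @ (inv_mass * r_plus)) >= 0
            )
            depth += 1
        if depth >= max_treedepth:
            stats.max_treedepth_hits += 1

        if not np.array_equal(theta_prop, theta):
            theta = theta_prop
            logp, grad = logp_grad(theta)

        accept_prob = alpha_stat / max(n_alpha, 1)
        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            window.append(theta.copy())
            if checkpoints and da_count == checkpoints[0]:
                checkpoints.pop(0)
                arr = np.asarray(window)
                if len(arr) >= 10:
                    var = arr.var(axis=0, ddof=1)
                    n = len(arr)
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    inv_mass = np.clip(inv_mass, 1e-8, None)
                window = []
                # re-initialise step-size search for the new metric
                eps = _find_initial_step(logp_grad, theta, rng, inv_mass)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
        else:
            if it == n_warmup:
                eps = float(np.exp(log_eps_bar)) if da_count > 0 else eps
            draws[it - n_warmup] = theta
            accept_sum += accept_prob
            accept_n += 1

    stats.step_size = eps
    stats.accept_mean = accept_sum / max(accept_n, 1)
    del stats.extra["treedepth"]
    return draws, stats


def nuts_sample(
    logp_grad,
    dim: int,
    config: SamplerConfig,
    rng_seed,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, list[NutsStats]]:
    """Run ``config.chains`` independent chains.

    Returns post-warmup draws of shape ``(chains, iterations - warmup, dim)``
    plus per-chain adaptation statistics.  Chains use independent streams
    spawned from ``rng_seed``, so results are reproducible bit-for-bit.
    """
    seeds = np.random.SeedSequence(rng_seed).spawn(config.chains)
    all_draws = np.empty((config.chains, config.iterations - config.warmup, dim))
    all_stats = []
    for c, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        theta0 = (
            np.asarray(init, dtype=float)
            if init is not None
            else 0.1 * rng.standard_normal(dim)
        )
        draws, stats = _nuts_chain(
            logp_grad,
            theta0,
            config.iterations,
            config.warmup,
            rng,
            config.target_accept,
            config.max_treedepth,
        )
        all_draws[c] = draws
        all_stats.append(stats)
    return all_draws, all_stats
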