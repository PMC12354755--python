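"""Convergence diagnostics and posterior predictive checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rlpupil.qlearning import AgentParameters, simulate_choices
from rlpupil.inference.samples import PosteriorSamples

__all__ = ["rhat", "convergence_report", "posterior_predictive_check", "PPCResult"]

RHAT_THRESHOLD = 1.1


def rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction statistic for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half
    before computing the classic between/within variance ratio.  A constant
    parameter yields NaN (flagged, not an error).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    if chains.shape[1] < 4:
        raise ValueError("need >= 4 draws per chain")
    n_half = chains.shape[1] // 2
    split = np.concatenate(
        [chains[:, :n_half], chains[:, n_half : 2 * n_half]], axis=0
    )
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return float("nan")
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def convergence_report(samples: PosteriorSamples) -> pd.DataFrame:
    """Split R-hat for every scalar coordinate of every parameter.

    Returns a tidy frame with a ``converged`` flag per parameter
    (R-hat < 1.1; NaN counts as converged-degenerate and is flagged).
    """
    rows = []
    for name, arr in samples.draws.items():
        if arr.ndim == 2:
            coords = {name: arr}
        else:
            coords = {
                f"{name}[{pid}]": arr[:, :, j]
                for j, pid in enumerate(samples.participant_ids)
            }
        for cname, carr in coords.items():
            r = rhat(carr)
            rows.append(
                {
                    "parameter": cname,
                    "rhat": r,
                    "converged": bool(r < RHAT_THRESHOLD) if np.isfinite(r) else False,
                    "degenerate": not np.isfinite(r),
                }
            )
    return pd.DataFrame(rows)


def max_rhat(samples: PosteriorSamples) -> float:
    report = convergence_report(samples)
    return float(np.nanmax(report["rhat"].to_numpy()))


@dataclass
class PPCResult:
    bin_edges: np.ndarray
    observed: np.ndarray  # (n_bins,) cohort-mean hit rate per trial bin
    replicated: np.ndarray  # (n_rep, n_bins)
    coverage: float  # fraction of bins inside the central 89% interval


def _binned_hit_curve(choices_by_session, n_trials: int, n_bins: int) -> np.ndarray:
    edges = np.linspace(0, n_trials, n_bins + 1).astype(int)
    curves = []
    for choices in choices_by_session:
        hit = (np.asarray(choices) == 0).astype(float)
        curves.append([hit[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return np.asarray(curves).mean(axis=0)


def posterior_predictive_check(
    samples: PosteriorSamples,
    data,
    schedules: dict,
    n_rep: int = 200,
    rng_seed=None,
    n_bins: int = 8,
    interval: float = 0.89,
) -> PPCResult:
    """Replicate datasets from random posterior draws on the observed
    schedules and compare binned cohort-mean hit-rate curves.

    ``schedules`` maps ``(participant_id, drug_state)`` to the TaskSchedule
    that generated (or would regenerate) the session.  Coverage is the
    fraction of trial bins whose observed value falls inside the central
    ``interval`` of the replicated distribution.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(rng_seed)
    condition = samples.condition
    drug_states = (
        ("placebo", "atomoxetine") if samples.design == "crossover" else ("none",)
    )

    sessions = []  # (pid, drug, observed choices, correct/incorrect outcome arrays)
    n_trials = None
    for pid in samples.participant_ids:
        for drug in drug_states:
            choices, _ = data.sequence(pid, drug, condition)
            co, io = schedules[(pid, drug)].condition_outcomes(condition)
            sessions.append((pid, drug, choices, co, io))
            n_trials = len(co)

    observed = _binned_hit_curve([s[2] for s in sessions], n_trials, n_bins)

    nat = {
        drug: {
            p: samples.participant_natural(p, drug if samples.design == "crossover" else "none")
            for p in ("alpha", "beta")
        }
        for drug in drug_states
    }
    total_draws = samples.n_chains * samples.n_draws
    draw_idx = rng.integers(0, total_draws, size=n_rep)

    replicated = np.empty((n_rep, n_bins))
    for k, d in enumerate(draw_idx):
        rep_choices = []
        for j, (pid, drug, _, co, io) in enumerate(sessions):
            p = samples.participant_ids.index(pid)
            params = AgentParameters(
                float(nat[drug]["alpha"][d, p]), float(nat[drug]["beta"][d, p])
            )
            choices, _ = simulate_choices(params, co, io, rng)
            rep_choices.append(choices)
        replicated[k] = _binned_hit_curve(rep_choices, n_trials, n_bins)

    lo = np.quantile(replicated, (1 - interval) / 2, axis=0)
    hi = np.quantile(replicated, 1 - (1 - interval) / 2, axis=0)
    coverage = float(np.mean((observed >= lo) & (observed <= hi)))
    return PPCResult(
        bin_edges=np.linspace(0, n_trials, n_bins + 1),
        observed=observed,
        replicated=replicated,
        coverage=coverage,
    )
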