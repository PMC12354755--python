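"""Posterior summaries and joint-parameter-space analyses.

Implements the probability of direction, highest density interval, region
of practical equivalence (0 +/- 0.1 x group SD), draw-wise drug contrasts,
the optimal (alpha, beta) grid simulation and the per-draw Euclidean
distance to the optimal point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rlpupil.qlearning import ALPHA_BOUNDS, BETA_BOUNDS
from rlpupil.synth.schedule import ScheduleConfig, generate_task_schedule
from rlpupil.inference.samples import PosteriorSamples

__all__ = [
    "probability_of_direction",
    "hdi",
    "rope_fraction",
    "ContrastPosterior",
    "drug_contrast",
    "summarize",
    "GridSpec",
    "OptimalPoint",
    "simulate_optimal_grid",
    "joint_distance_posterior",
    "joint_distance_contrast",
]

ROPE_SD_MULTIPLE = 0.1
REJECT_BELOW = 2.5  # % in ROPE
ACCEPT_ABOVE = 97.5
DEFAULT_HDI_MASS = 0.89


def probability_of_direction(posterior: np.ndarray) -> float:
    """Percent of draws strictly positive or strictly negative, whichever is
    greater.  Exact zeros count toward neither side."""
    x = np.asarray(posterior, dtype=float)
    if x.size == 0:
        raise ValueError("empty posterior vector")
    p_pos = np.mean(x > 0)
    p_neg = np.mean(x < 0)
    return float(100.0 * max(p_pos, p_neg))


def hdi(posterior: np.ndarray, mass: float = DEFAULT_HDI_MASS) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` sorted
    draws.  Ties on width resolve to the smallest lower bound."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(posterior, dtype=float))
    n = x.size
    if n < int(np.ceil(1.0 / (1.0 - mass))):
        raise ValueError("too few draws for the requested mass")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> smallest lower bound
    return float(x[i]), float(x[i + m - 1])


def rope_fraction(
    posterior: np.ndarray, group_sd_point_estimate: float
) -> tuple[float, str]:
    """Percent of the posterior inside [-0.1 SD, +0.1 SD] and the decision.

    Labels: ``reject-null`` below 2.5%, ``accept-null`` above 97.5%, else
    ``undecided``.
    """
    if not group_sd_point_estimate > 0:
        raise ValueError("group SD point estimate must be positive")
    x = np.asarray(posterior, dtype=float)
    if x.size == 0:
        raise ValueError("empty posterior vector")
    half_width = ROPE_SD_MULTIPLE * group_sd_point_estimate
    pct = float(100.0 * np.mean((x >= -half_width) & (x <= half_width)))
    if pct < REJECT_BELOW:
        label = "reject-null"
    elif pct > ACCEPT_ABOVE:
        label = "accept-null"
    else:
        label = "undecided"
    return pct, label


@dataclass
class ContrastPosterior:
    """Draw-wise atomoxetine-minus-placebo difference of a group mean."""

    values: np.ndarray
    label: str


def drug_contrast(samples: PosteriorSamples, parameter: str) -> ContrastPosterior:
    """Draw-wise natural-scale group-mean contrast (atomoxetine - placebo).

    Computed per MCMC draw, never from posterior summaries.
    """
    if samples.design != "crossover":
        raise ValueError("drug contrasts require a crossover-design fit")
    atx = samples.group_natural_mean(parameter, "atomoxetine")
    pla = samples.group_natural_mean(parameter, "placebo")
    return ContrastPosterior(
        values=atx - pla, label=f"delta_{parameter}_{samples.condition}"
    )


def summarize(
    posterior: np.ndarray,
    group_sd_point_estimate: float | None = None,
    mass: float = DEFAULT_HDI_MASS,
) -> dict:
    """Median, HDI, p_dir and (optionally) ROPE summary of a sample vector."""
    x = np.asarray(posterior, dtype=float)
    lo, hi = hdi(x, mass)
    out = {
        "median": float(np.median(x)),
        "hdi_low": lo,
        "hdi_high": hi,
        "hdi_mass": mass,
        "p_dir": probability_of_direction(x),
    }
    if group_sd_point_estimate is not None:
        pct, label = rope_fraction(x, group_sd_point_estimate)
        out["rope_percent"] = pct
        out["rope_decision"] = label
    return out


# -- optimal-strategy grid simulation -------------------------------------


@dataclass(frozen=True)
class GridSpec:
    alpha_step: float = 0.02
    beta_step: float = 0.25

    def alpha_grid(self) -> np.ndarray:
        n = int(round((ALPHA_BOUNDS[1] - ALPHA_BOUNDS[0]) / self.alpha_step))
        return np.linspace(*ALPHA_BOUNDS, n + 1)

    def beta_grid(self) -> np.ndarray:
        n = int(round((BETA_BOUNDS[1] - BETA_BOUNDS[0]) / self.beta_step))
        return np.linspace(*BETA_BOUNDS, n + 1)


@dataclass
class OptimalPoint:
    alpha_star: float
    beta_star: float
    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    hit_rate_surface: np.ndarray  # (n_alpha, n_beta)
    condition: str = "gain"
    meta: dict = field(default_factory=dict)


def _cell_hit_rate(
    alpha: float,
    beta: float,
    correct: np.ndarray,
    incorrect: np.ndarray,
    uniforms: np.ndarray,
) -> float:
    """Mean hit rate of a batch of agents sharing common random numbers.

    ``correct``/``incorrect``/``uniforms`` are (n_agents, n_trials) arrays;
    the same schedules and choice uniforms are reused for every grid cell,
    which removes most Monte-Carlo noise from between-cell comparisons.
    """
    A, T = correct.shape
    q0 = np.zeros(A)
    q1 = np.zeros(A)
    hits = 0.0
    for t in range(T):
        z = beta * (q0 - q1)
        p0 = 1.0 / (1.0 + np.exp(-z))
        choose0 = uniforms[:, t] < p0
        hits += choose0.sum()
        r = np.where(choose0, correct[:, t], incorrect[:, t])
        q0 = np.where(choose0, q0 + alpha * (r - q0), q0)
        q1 = np.where(~choose0, q1 + alpha * (r - q1), q1)
    return float(hits / (A * T))


def simulate_optimal_grid(
    schedule_config: ScheduleConfig | None = None,
    grid_spec: GridSpec | None = None,
    n_agents_per_cell: int = 1000,
    rng_seed=None,
    condition: str = "gain",
) -> OptimalPoint:
    """Mean simulated hit rate over an (alpha, beta) grid; the argmax cell
    is the "optimal" strategy for the task.

    All cells share one set of ``n_agents_per_cell`` schedules and choice
    uniforms (common random numbers), so the surface is smooth and the
    argmax is stable at a given seed.
    """
    cfg = schedule_config or ScheduleConfig()
    spec = grid_spec or GridSpec()
    if n_agents_per_cell < 1:
        raise ValueError("n_agents_per_cell must be >= 1")
    alphas = spec.alpha_grid()
    betas = spec.beta_grid()
    if alphas.size * betas.size < 2:
        raise ValueError("degenerate grid")

    rng = np.random.default_rng(rng_seed)
    schedules = [generate_task_schedule(cfg, rng) for _ in range(n_agents_per_cell)]
    pairs = [s.condition_outcomes(condition) for s in schedules]
    correct = np.stack([p[0] for p in pairs])
    incorrect = np.stack([p[1] for p in pairs])
    uniforms = rng.random(correct.shape)

    surface = np.empty((alphas.size, betas.size))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            surface[i, j] = _cell_hit_rate(a, b, correct, incorrect, uniforms)

    i_star, j_star = np.unravel_index(np.argmax(surface), surface.shape)
    return OptimalPoint(
        alpha_star=float(alphas[i_star]),
        beta_star=float(betas[j_star]),
        alpha_grid=alphas,
        beta_grid=betas,
        hit_rate_surface=surface,
        condition=condition,
        meta={"n_agents_per_cell": n_agents_per_cell},
    )


# -- joint parameter space --------------------------------------------------


def joint_distance_posterior(
    samples: PosteriorSamples, optimal: OptimalPoint, drug_state: str
) -> np.ndarray:
    """Per-draw Euclidean distance between the natural-scale group mean
    (alpha, beta) and the optimal point, in raw natural units."""
    a = samples.group_natural_mean("alpha", drug_state)
    b = samples.group_natural_mean("beta", drug_state)
    return np.sqrt((a - optimal.alpha_star) ** 2 + (b - optimal.beta_star) ** 2)


def joint_distance_contrast(
    samples: PosteriorSamples, optimal: OptimalPoint
) -> ContrastPosterior:
    """Draw-wise distance(atomoxetine) - distance(placebo); negative values
    mean the drug state sits closer to the optimal strategy."""
    d_atx = joint_distance_posterior(samples, optimal, "atomoxetine")
    d_pla = joint_distance_posterior(samples, optimal, "placebo")
    return ContrastPosterior(
        values=d_atx - d_pla, label=f"delta_distance_{samples.condition}"
    )
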