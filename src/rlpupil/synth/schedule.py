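"""Probabilistic gain/loss task schedules.

The default design: 96 trials, 48 gain and 48 loss, presented in randomised
order within consecutive blocks of 12 (6 gain + 6 loss each).  In the gain
condition the advantageous option wins +0.50 with probability 0.75 (else 0)
and the disadvantageous option wins with probability 0.25.  In the loss
condition the advantageous option loses nothing with probability 0.75 (else
-0.50) and the disadvantageous option loses -0.50 with probability 0.75.
Outcome assignments are drawn i.i.d. per trial by default; ``exact_counts``
switches to an exact-count realisation per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WIN = 0.5
LOSS = -0.5
NIL = 0.0


@dataclass(frozen=True)
class ScheduleConfig:
    trials_per_condition: int = 48
    block_size: int = 12
    contingency: float = 0.75
    reward_magnitude: float = 0.5
    conditions: tuple[str, ...] = ("gain", "loss")
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.contingency <= 1.0:
            raise ValueError("contingency must be a probability")
        n_cond = len(self.conditions)
        if self.block_size % n_cond != 0:
            raise ValueError("block_size must divide evenly across conditions")
        per_block = self.block_size // n_cond
        if self.trials_per_condition % per_block != 0:
            raise ValueError(
                "trials_per_condition must be divisible into blocks of "
                f"{per_block} per condition"
            )


@dataclass
class TaskSchedule:
    """Ordered trial list with per-trial latent outcome assignments.

    ``correct_outcome[t]`` is the outcome delivered if the advantageous
    option (action 0) is chosen on trial ``t``; ``incorrect_outcome[t]`` if
    the other option is chosen.
    """

    condition: np.ndarray  # (n,) of 'gain'/'loss'
    correct_outcome: np.ndarray  # (n,) float
    incorrect_outcome: np.ndarray  # (n,) float
    block_size: int
    config: ScheduleConfig = field(default_factory=ScheduleConfig)

    def __len__(self) -> int:
        return len(self.condition)

    def conditions(self) -> tuple[str, ...]:
        return self.config.conditions

    def condition_outcomes(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-condition (correct, incorrect) outcome arrays in trial order."""
        mask = self.condition == condition
        return self.correct_outcome[mask], self.incorrect_outcome[mask]


def _condition_outcomes(
    condition: str, n: int, cfg: ScheduleConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Realise the 75/25 contingency for one condition.

    Gain: good outcome is +magnitude, bad is 0.  Loss: good outcome is 0,
    bad is -magnitude.  The advantageous option receives the good outcome
    with probability ``contingency``; the other option with
    ``1 - contingency``.
    """
    if condition == "gain":
        good, bad = cfg.reward_magnitude, NIL
    elif condition == "loss":
        good, bad = NIL, -cfg.reward_magnitude
    else:
        raise ValueError(f"unknown condition {condition!r}")

    def draw(p: float) -> np.ndarray:
        if cfg.exact_counts:
            k = int(round(p * n))
            flags = np.zeros(n, dtype=bool)
            flags[:k] = True
            rng.shuffle(flags)
        else:
            flags = rng.random(n) < p
        return np.where(flags, good, bad)

    return draw(cfg.contingency), draw(1.0 - cfg.contingency)


def generate_task_schedule(
    config: ScheduleConfig | None = None, rng_seed=None
) -> TaskSchedule:
    """Generate one schedule: block-randomised condition order plus latent
    per-trial outcome assignments for both options."""
    cfg = config or ScheduleConfig()
    rng = np.random.default_rng(rng_seed)
    n_cond = len(cfg.conditions)
    per_block = cfg.block_size // n_cond
    n_blocks = cfg.trials_per_condition // per_block

    order = []
    for _ in range(n_blocks):
        block = np.repeat(np.arange(n_cond), per_block)
        rng.shuffle(block)
        order.append(block)
    cond_idx = np.concatenate(order)
    condition = np.asarray(cfg.conditions, dtype=object)[cond_idx]

    correct = np.empty(len(condition))
    incorrect = np.empty(len(condition))
    for ci, cname in enumerate(cfg.conditions):
        mask = cond_idx == ci
        co, io = _condition_outcomes(cname, int(mask.sum()), cfg, rng)
        correct[mask] = co
        incorrect[mask] = io
    return TaskSchedule(
        condition=condition,
        correct_outcome=correct,
        incorrect_outcome=incorrect,
        block_size=cfg.block_size,
        config=cfg,
    )
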