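"""Cohorts of simulated crossover participants with known ground truth.

Each participant's probit-scale parameters are drawn non-centred:
``alpha' = mu_alpha + sigma_alpha * nu_alpha`` with ``nu ~ N(0, 1)``, and
likewise for ``beta'`` and the drug offsets ``delta_alpha``/``delta_beta``.
Natural-scale parameters come from the probit transforms; the atomoxetine
session adds the offsets before the CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from rlpupil.qlearning import AgentParameters, ChoiceDataset, simulate_choices
from rlpupil.synth.schedule import ScheduleConfig, TaskSchedule, generate_task_schedule
from rlpupil.transforms import transform_to_natural

PARAM_NAMES = ("alpha", "beta", "delta_alpha", "delta_beta")


@dataclass(frozen=True)
class GroupHyperParameters:
    """Probit-scale group-level means and SDs for one task condition."""

    mu_alpha: float = -1.0
    mu_beta: float = 0.0
    sigma_alpha: float = 0.3
    sigma_beta: float = 0.3
    mu_delta_alpha: float = 0.0
    mu_delta_beta: float = 0.0
    sigma_delta_alpha: float = 0.2
    sigma_delta_beta: float = 0.2

    def __post_init__(self) -> None:
        for name in ("sigma_alpha", "sigma_beta", "sigma_delta_alpha", "sigma_delta_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortGroundTruth:
    """Per-condition hyperparameters for the generating distribution."""

    gain: GroupHyperParameters = field(default_factory=GroupHyperParameters)
    loss: GroupHyperParameters = field(default_factory=GroupHyperParameters)

    def for_condition(self, condition: str) -> GroupHyperParameters:
        if condition not in ("gain", "loss"):
            raise ValueError(f"unknown condition {condition!r}")
        return getattr(self, condition)

    def to_dict(self) -> dict:
        return {"gain": asdict(self.gain), "loss": asdict(self.loss)}


@dataclass
class CohortResult:
    """Simulated behaviour plus the exact parameter values used."""

    data: ChoiceDataset
    participants: pd.DataFrame  # one row per participant x condition x drug_state
    schedules: dict  # (participant_id, drug_state) -> TaskSchedule
    truth: CohortGroundTruth


def _participant_natural(
    hp: GroupHyperParameters, nu: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Natural (alpha, beta) per drug state from one participant's nu draws."""
    a_p = hp.mu_alpha + hp.sigma_alpha * nu[0]
    b_p = hp.mu_beta + hp.sigma_beta * nu[1]
    d_a = hp.mu_delta_alpha + hp.sigma_delta_alpha * nu[2]
    d_b = hp.mu_delta_beta + hp.sigma_delta_beta * nu[3]
    out = {}
    for drug in ("placebo", "atomoxetine"):
        a, b = transform_to_natural(a_p, b_p, drug, d_a, d_b)
        out[drug] = (float(a), float(b))
    return out


def generate_cohort_behaviour(
    truth: CohortGroundTruth,
    n_participants: int,
    schedule_config: ScheduleConfig | None = None,
    rng_seed=None,
) -> CohortResult:
    """Simulate a placebo/atomoxetine crossover cohort.

    Each participant gets an independent schedule per drug session.  Returns
    the pooled trial table, the exact natural-scale parameters used, and the
    schedules (needed for posterior predictive checks).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    cfg = schedule_config or ScheduleConfig()
    rng = np.random.default_rng(rng_seed)

    frames, rows, schedules = [], [], {}
    for i in range(n_participants):
        pid = f"p{i:03d}"
        nu = {c: rng.standard_normal(4) for c in ("gain", "loss")}
        for drug in ("placebo", "atomoxetine"):
            schedule = generate_task_schedule(cfg, rng_seed=rng)
            schedules[(pid, drug)] = schedule
            for condition in cfg.conditions:
                hp = truth.for_condition(condition)
                alpha, beta = _participant_natural(hp, nu[condition])[drug]
                co, io = schedule.condition_outcomes(condition)
                choices, outcomes = simulate_choices(
                    AgentParameters(alpha, beta), co, io, rng
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "drug_state": drug,
                            "condition": condition,
                            "trial": np.arange(len(choices)),
                            "action": choices,
                            "outcome": outcomes,
                            "rt": np.nan,
                        }
                    )
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "drug_state": drug,
                        "condition": condition,
                        "alpha": alpha,
                        "beta": beta,
                        "nu_alpha": nu[condition][0],
                        "nu_beta": nu[condition][1],
                        "nu_delta_alpha": nu[condition][2],
                        "nu_delta_beta": nu[condition][3],
                    }
                )

    data = ChoiceDataset(pd.concat(frames, ignore_index=True))
    participants = pd.DataFrame(rows)
    return CohortResult(data=data, participants=participants, schedules=schedules, truth=truth)
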