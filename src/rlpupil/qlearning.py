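"""Delta-rule value updating, softmax action selection, agent simulation
and choice log-likelihood.

The generative model has two free parameters per participant, condition and
drug state: a learning rate ``alpha`` in [0, 1] weighting the prediction
error, and an inverse temperature ``beta`` in [0, 10] controlling choice
determinism.  Outcomes are coded in pounds (+0.5 / 0 for gain trials,
-0.5 / 0 for loss trials), so ``beta`` operates on that monetary scale.
Q-values are initialised to 0 for every (stimulus, action) pair, making the
first choice uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
    "AgentParameters",
    "ChoiceDataset",
    "rescorla_wagner_update",
    "softmax_probability",
    "simulate_agent",
    "simulate_choices",
    "choice_log_likelihood",
    "sequence_log_likelihood",
    "hit_rate",
]

ALPHA_BOUNDS = (0.0, 1.0)
BETA_BOUNDS = (0.0, 10.0)

#: canonical column order of the trial-table CSV format
CHOICE_COLUMNS = [
    "participant_id",
    "drug_state",
    "condition",
    "trial",
    "action",
    "outcome",
    "rt",
]

DRUG_STATES = ("placebo", "atomoxetine", "none")
CONDITIONS = ("gain", "loss")


@dataclass(frozen=True)
class AgentParameters:
    """Natural-scale Q-learning parameters for one participant/session.

    Raises ``ValueError`` at construction when a bound is violated: the
    bounds are part of the model definition, not soft conventions.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]) or not math.isfinite(
            self.alpha
        ):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha!r}")
        if not (BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]) or not math.isfinite(
            self.beta
        ):
            raise ValueError(f"beta must be in [0, 10], got {self.beta!r}")


class ChoiceDataset:
    """Long-format trial table: one row per task trial.

    Thin, validating wrapper around a :class:`pandas.DataFrame` with columns
    ``participant_id, drug_state, condition, trial, action, outcome, rt``.
    ``action`` is 0/1 (0 = the advantageous option by convention of the
    synthetic task; for observed data it is an arbitrary but fixed stimulus
    label).  ``rt`` may be NaN; trials with missing action (no response) are
    stored with ``action`` = -1 and are excluded from likelihoods.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.loc[:, CHOICE_COLUMNS].copy()
        df["trial"] = df["trial"].astype(int)
        df["action"] = df["action"].astype(int)
        df["outcome"] = df["outcome"].astype(float)
        if not df["drug_state"].isin(DRUG_STATES).all():
            raise ValueError("drug_state must be one of " + ", ".join(DRUG_STATES))
        if not df["condition"].isin(CONDITIONS).all():
            raise ValueError("condition must be 'gain' or 'loss'")
        dup = df.duplicated(["participant_id", "drug_state", "condition", "trial"])
        if dup.any():
            raise ValueError("duplicate trial index within participant/session/condition")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChoiceDataset) and self.df.equals(other.df)

    def sequence(
        self, participant_id, drug_state: str, condition: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (choices, outcomes) for one session ordered by trial index.

        No-response trials (action < 0) are dropped.
        """
        sub = self.df[
            (self.df["participant_id"] == participant_id)
            & (self.df["drug_state"] == drug_state)
            & (self.df["condition"] == condition)
        ].sort_values("trial")
        sub = sub[sub["action"] >= 0]
        return sub["action"].to_numpy(np.int64), sub["outcome"].to_numpy(np.float64)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ChoiceDataset":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, parts) -> "ChoiceDataset":
        return cls(pd.concat([p.df for p in parts], ignore_index=True))


def rescorla_wagner_update(q: float, alpha: float, r: float) -> float:
    """One delta-rule step: ``q + alpha * (r - q)``."""
    if not (math.isfinite(q) and math.isfinite(r)):
        raise ValueError("q and r must be finite")
    if not (ALPHA_BOUNDS[0] <= alpha <= ALPHA_BOUNDS[1]):
        raise ValueError(f"alpha must be in [0, 1], got {alpha!r}")
    return q + alpha * (r - q)


def softmax_probability(q_chosen: float, q_alternative: float, beta: float) -> float:
    """Probability of the chosen action under the two-option softmax.

    Computed via the logistic of ``beta * (q_chosen - q_alternative)`` which
    is the numerically stable (max-subtracted) form of the two-term softmax.
    """
    if not (BETA_BOUNDS[0] <= beta <= BETA_BOUNDS[1]):
        raise ValueError(f"beta must be in [0, 10], got {beta!r}")
    if not (math.isfinite(q_chosen) and math.isfinite(q_alternative)):
        raise ValueError("Q-values must be finite")
    z = beta * (q_chosen - q_alternative)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def simulate_choices(
    params: AgentParameters,
    correct_outcomes: np.ndarray,
    incorrect_outcomes: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate one agent on a per-trial outcome schedule.

    ``correct_outcomes[t]`` / ``incorrect_outcomes[t]`` are the outcomes the
    agent receives on trial ``t`` if it picks action 0 (the advantageous
    option) / action 1.  Returns ``(choices, outcomes)`` arrays.
    """
    correct_outcomes = np.asarray(correct_outcomes, dtype=float)
    incorrect_outcomes = np.asarray(incorrect_outcomes, dtype=float)
    n = len(correct_outcomes)
    if n == 0:
        raise ValueError("empty schedule")
    q = np.zeros(2)
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=float)
    for t in range(n):
        p0 = softmax_probability(q[0], q[1], params.beta)
        a = 0 if rng.random() < p0 else 1
        r = correct_outcomes[t] if a == 0 else incorrect_outcomes[t]
        q[a] = rescorla_wagner_update(q[a], params.alpha, r)
        choices[t] = a
        outcomes[t] = r
    return choices, outcomes


def simulate_agent(
    params: AgentParameters,
    schedule,
    rng_seed,
    participant_id="sim",
    drug_state: str = "none",
) -> ChoiceDataset:
    """Simulate an agent on a :class:`~rlpupil.synth.schedule.TaskSchedule`
    (or anything exposing ``condition_outcomes(condition)``).

    Each condition is simulated with its own Q-table; the per-condition
    parameters are identical (pass per-condition params by calling once per
    condition with a restricted schedule if needed).
    """
    rng = np.random.default_rng(rng_seed)
    frames = []
    for condition in schedule.conditions():
        co, io = schedule.condition_outcomes(condition)
        choices, outcomes = simulate_choices(params, co, io, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "drug_state": drug_state,
                    "condition": condition,
                    "trial": np.arange(len(choices)),
                    "action": choices,
                    "outcome": outcomes,
                    "rt": np.nan,
                }
            )
        )
    if not frames:
        raise ValueError("schedule has no trials")
    return ChoiceDataset(pd.concat(frames, ignore_index=True))


def sequence_log_likelihood(
    choices: np.ndarray, outcomes: np.ndarray, alpha: float, beta: float
) -> float:
    """Log-likelihood (nats) of one ordered choice/outcome sequence."""
    if not (ALPHA_BOUNDS[0] <= alpha <= ALPHA_BOUNDS[1]):
        raise ValueError("alpha out of bounds")
    if not (BETA_BOUNDS[0] <= beta <= BETA_BOUNDS[1]):
        raise ValueError("beta out of bounds")
    q = np.zeros(2)
    ll = 0.0
    for a, r in zip(choices, outcomes):
        z = beta * (q[a] - q[1 - a])
        # log sigmoid, stable on both tails
        ll += -np.log1p(np.exp(-abs(z))) + min(z, 0.0)
        q[a] += alpha * (r - q[a])
    return float(ll)


def choice_log_likelihood(data: ChoiceDataset, params: AgentParameters) -> float:
    """Total log-likelihood of a single participant's trial table.

    The table must contain exactly one (participant, drug_state) pair; each
    condition is evaluated with a fresh Q-table.
    """
    keys = data.df[["participant_id", "drug_state"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("expected a single participant x drug_state table")
    pid, drug = keys.iloc[0]
    total = 0.0
    for condition in data.df["condition"].unique():
        sub = data.df[data.df["condition"] == condition]
        trials = sub["trial"].to_numpy()
        if len(np.unique(trials)) != len(trials):
            raise ValueError("duplicate trial indices")
        choices, outcomes = data.sequence(pid, drug, condition)
        total += sequence_log_likelihood(choices, outcomes, params.alpha, params.beta)
    return total


def hit_rate(data: ChoiceDataset, correct_action: int = 0) -> float:
    """Fraction of responded trials on which the advantageous option was
    chosen.  No-response trials are excluded from the denominator."""
    responded = data.df[data.df["action"] >= 0]
    if len(responded) == 0:
        return math.nan
    return float((responded["action"] == correct_action).mean())
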