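"""Non-centred hierarchical Q-learning model: joint log-density + gradient.

Two designs are supported, fit separately per task condition:

* ``single_session`` — one session per participant (e.g. unmedicated
  controls): group mean ``mu`` and SD ``sigma`` per parameter plus
  participant deviations ``nu``; natural scale via the probit transform.
* ``crossover`` — placebo and atomoxetine sessions per participant, with
  additional group-level drug-offset locations/scales (``mu_delta``,
  ``sigma_delta``) and per-participant offset deviations.  The placebo path
  ignores the offsets; the atomoxetine path adds them before the CDF.

Priors: standard normal on all ``mu`` and ``nu``; half-normal(0, 1) on all
``sigma``.  Group SDs are sampled on the log scale with the Jacobian folded
into the log-density, so the parameter vector is fully unconstrained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from rlpupil.qlearning import ChoiceDataset
from rlpupil.inference.loglik import batch_loglik_grad

BETA_SCALE = 10.0
_LOG_HALF_NORMAL_CONST = 0.5 * math.log(2.0 / math.pi)

DESIGNS = ("single_session", "crossover")
CROSSOVER_STATES = ("placebo", "atomoxetine")


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


@dataclass
class QLearningHierarchicalModel:
    """Differentiable joint log-density for one condition's choice data."""

    design: str
    condition: str
    participant_ids: list
    choices: np.ndarray  # (n_sessions, max_trials)
    outcomes: np.ndarray
    lengths: np.ndarray  # (n_sessions,)
    n_participants: int = field(init=False)

    # unconstrained vector layout:
    #   single_session: [mu_a, mu_b, s_a, s_b, nu_a(P), nu_b(P)]
    #   crossover:      [mu_a, mu_b, mu_da, mu_db, s_a, s_b, s_da, s_db,
    #                    nu_a(P), nu_b(P), nu_da(P), nu_db(P)]
    # where s_* = log(sigma_*); sessions are ordered participant-major,
    # placebo before atomoxetine in the crossover design.

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        self.n_participants = len(self.participant_ids)
        per = 2 if self.design == "crossover" else 1
        if self.choices.shape[0] != per * self.n_participants:
            raise ValueError("session count inconsistent with design")

    # -- vector layout ----------------------------------------------------
    @property
    def n_group_params(self) -> int:
        return 8 if self.design == "crossover" else 4

    @property
    def n_participant_blocks(self) -> int:
        return 4 if self.design == "crossover" else 2

    @property
    def dim(self) -> int:
        return self.n_group_params + self.n_participant_blocks * self.n_participants

    def parameter_names(self) -> list[str]:
        """Flat names, one per unconstrained coordinate (sigma reported on
        its natural positive scale when draws are unpacked)."""
        if self.design == "crossover":
            group = [
                "mu_alpha", "mu_beta", "mu_delta_alpha", "mu_delta_beta",
                "sigma_alpha", "sigma_beta", "sigma_delta_alpha", "sigma_delta_beta",
            ]
            blocks = ["nu_alpha", "nu_beta", "nu_delta_alpha", "nu_delta_beta"]
        else:
            group = ["mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta"]
            blocks = ["nu_alpha", "nu_beta"]
        names = list(group)
        for b in blocks:
            names += [f"{b}[{pid}]" for pid in self.participant_ids]
        return names

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Split an unconstrained vector (or (..., dim) array) into named
        components, exponentiating the log-SDs."""
        theta = np.asarray(theta)
        P = self.n_participants
        g = self.n_group_params
        out: dict[str, np.ndarray] = {}
        if self.design == "crossover":
            keys_mu = ["mu_alpha", "mu_beta", "mu_delta_alpha", "mu_delta_beta"]
            keys_sig = ["sigma_alpha", "sigma_beta", "sigma_delta_alpha", "sigma_delta_beta"]
            keys_nu = ["nu_alpha", "nu_beta", "nu_delta_alpha", "nu_delta_beta"]
        else:
            keys_mu = ["mu_alpha", "mu_beta"]
            keys_sig = ["sigma_alpha", "sigma_beta"]
            keys_nu = ["nu_alpha", "nu_beta"]
        for k, key in enumerate(keys_mu):
            out[key] = theta[..., k]
        for k, key in enumerate(keys_sig):
            out[key] = np.exp(theta[..., len(keys_mu) + k])
        for k, key in enumerate(keys_nu):
            out[key] = theta[..., g + k * P : g + (k + 1) * P]
        return out

    # -- log density ------------------------------------------------------
    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log-density and gradient at an unconstrained point."""
        P = self.n_participants
        g = self.n_group_params
        grad = np.zeros_like(theta)
        crossover = self.design == "crossover"

        n_mu = 4 if crossover else 2
        mu = theta[:n_mu]
        s = theta[n_mu:g]
        sigma = np.exp(s)
        nu = theta[g:].reshape(self.n_participant_blocks, P)

        # priors: N(0,1) on mu and nu; half-normal(0,1) on sigma (+ Jacobian)
        logp = -0.5 * float(mu @ mu) - 0.5 * float((nu * nu).sum())
        logp += float(np.sum(_LOG_HALF_NORMAL_CONST - 0.5 * sigma**2 + s))
        grad[:n_mu] = -mu
        grad[g:] = -nu.ravel()
        grad[n_mu:g] = -(sigma**2) + 1.0

        # participant probit-scale values
        a_base = mu[0] + sigma[0] * nu[0]
        b_base = mu[1] + sigma[1] * nu[1]
        if crossover:
            d_a = mu[2] + sigma[2] * nu[2]
            d_b = mu[3] + sigma[3] * nu[3]
            x_a = np.concatenate([a_base, a_base + d_a])  # placebo block, atx block
            x_b = np.concatenate([b_base, b_base + d_b])
            sess_order = np.concatenate([np.arange(P) * 2, np.arange(P) * 2 + 1])
        else:
            x_a, x_b = a_base, b_base
            sess_order = np.arange(P)

        alpha = ndtr(x_a)
        beta = ndtr(x_b) * BETA_SCALE

        ll, dla, dlb = batch_loglik_grad(
            self.choices[sess_order],
            self.outcomes[sess_order],
            self.lengths[sess_order],
            alpha,
            beta,
        )
        logp += float(ll.sum())

        g_xa = dla * _norm_pdf(x_a)
        g_xb = dlb * BETA_SCALE * _norm_pdf(x_b)

        if crossover:
            g_a_pl, g_a_at = g_xa[:P], g_xa[P:]
            g_b_pl, g_b_at = g_xb[:P], g_xb[P:]
            ga_base = g_a_pl + g_a_at
            gb_base = g_b_pl + g_b_at
            grad[0] += ga_base.sum()
            grad[1] += gb_base.sum()
            grad[2] += g_a_at.sum()
            grad[3] += g_b_at.sum()
            grad[4] += sigma[0] * float(nu[0] @ ga_base)
            grad[5] += sigma[1] * float(nu[1] @ gb_base)
            grad[6] += sigma[2] * float(nu[2] @ g_a_at)
            grad[7] += sigma[3] * float(nu[3] @ g_b_at)
            grad[g : g + P] += sigma[0] * ga_base
            grad[g + P : g + 2 * P] += sigma[1] * gb_base
            grad[g + 2 * P : g + 3 * P] += sigma[2] * g_a_at
            grad[g + 3 * P :] += sigma[3] * g_b_at
        else:
            grad[0] += g_xa.sum()
            grad[1] += g_xb.sum()
            grad[2] += sigma[0] * float(nu[0] @ g_xa)
            grad[3] += sigma[1] * float(nu[1] @ g_xb)
            grad[g : g + P] += sigma[0] * g_xa
            grad[g + P :] += sigma[1] * g_xb

        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]


def build_model(
    data: ChoiceDataset, condition: str, design: str = "crossover"
) -> QLearningHierarchicalModel:
    """Assemble the model for one condition from a long-format trial table.

    Under the crossover design every participant must contribute both a
    placebo and an atomoxetine session.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    df = data.df[data.df["condition"] == condition]
    if len(df) == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    participant_ids = sorted(df["participant_id"].unique())

    sequences = []
    if design == "crossover":
        for pid in participant_ids:
            states = set(df.loc[df["participant_id"] == pid, "drug_state"])
            missing = set(CROSSOVER_STATES) - states
            if missing:
                raise ValueError(
                    f"participant {pid!r} missing drug state(s) {sorted(missing)}"
                )
            for drug in CROSSOVER_STATES:
                sequences.append(data.sequence(pid, drug, condition))
    else:
        for pid in participant_ids:
            drug = df.loc[df["participant_id"] == pid, "drug_state"].iloc[0]
            sequences.append(data.sequence(pid, drug, condition))

    max_t = max(len(c) for c, _ in sequences)
    S = len(sequences)
    choices = np.zeros((S, max_t), dtype=np.int64)
    outcomes = np.zeros((S, max_t), dtype=np.float64)
    lengths = np.zeros(S, dtype=np.int64)
    for i, (c, o) in enumerate(sequences):
        choices[i, : len(c)] = c
        outcomes[i, : len(o)] = o
        lengths[i] = len(c)

    return QLearningHierarchicalModel(
        design=design,
        condition=condition,
        participant_ids=participant_ids,
        choices=choices,
        outcomes=outcomes,
        lengths=lengths,
    )
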