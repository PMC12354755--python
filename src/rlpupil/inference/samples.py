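"""Posterior draw container, natural-scale accessors and text round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from rlpupil.inference.model import BETA_SCALE, QLearningHierarchicalModel

__all__ = ["PosteriorSamples"]


@dataclass
class PosteriorSamples:
    """Post-warmup MCMC draws for one fitted condition model.

    ``draws`` maps parameter names to arrays of shape ``(chains, n_draws)``
    for group-level parameters or ``(chains, n_draws, n_participants)`` for
    the per-participant deviation blocks.  SDs are stored on the natural
    (positive) scale.
    """

    draws: dict[str, np.ndarray]
    design: str
    condition: str
    participant_ids: list
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains flattened."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @classmethod
    def from_unconstrained(
        cls,
        model: QLearningHierarchicalModel,
        theta_draws: np.ndarray,
        meta: dict | None = None,
    ) -> "PosteriorSamples":
        """Build from raw sampler output of shape (chains, draws, dim)."""
        unpacked = model.unpack(theta_draws)
        return cls(
            draws={k: np.asarray(v) for k, v in unpacked.items()},
            design=model.design,
            condition=model.condition,
            participant_ids=list(model.participant_ids),
            meta=dict(meta or {}),
        )

    # -- natural-scale accessors ------------------------------------------
    def _require(self, *names: str) -> None:
        for n in names:
            if n not in self.draws:
                raise KeyError(f"parameter {n!r} not present in this fit")

    def group_natural_mean(self, parameter: str, drug_state: str) -> np.ndarray:
        """Per-draw natural-scale group-level mean (flattened over chains).

        The group mean is the probit transform of the group-level location;
        the atomoxetine path adds the offset location before the CDF.
        """
        if parameter not in ("alpha", "beta"):
            raise KeyError(f"unknown parameter {parameter!r}")
        self._require(f"mu_{parameter}")
        loc = self.stacked(f"mu_{parameter}")
        if drug_state == "atomoxetine":
            self._require(f"mu_delta_{parameter}")
            loc = loc + self.stacked(f"mu_delta_{parameter}")
        elif drug_state not in ("placebo", "none"):
            raise ValueError(f"unknown drug_state {drug_state!r}")
        nat = ndtr(loc)
        return nat * BETA_SCALE if parameter == "beta" else nat

    def participant_natural(self, parameter: str, drug_state: str) -> np.ndarray:
        """Per-draw per-participant natural values, shape (total_draws, P)."""
        if parameter not in ("alpha", "beta"):
            raise KeyError(f"unknown parameter {parameter!r}")
        self._require(f"mu_{parameter}", f"sigma_{parameter}", f"nu_{parameter}")
        base = (
            self.stacked(f"mu_{parameter}")[:, None]
            + self.stacked(f"sigma_{parameter}")[:, None] * self.stacked(f"nu_{parameter}")
        )
        if drug_state == "atomoxetine":
            self._require(f"mu_delta_{parameter}")
            delta = (
                self.stacked(f"mu_delta_{parameter}")[:, None]
                + self.stacked(f"sigma_delta_{parameter}")[:, None]
                * self.stacked(f"nu_delta_{parameter}")
            )
            base = base + delta
        elif drug_state not in ("placebo", "none"):
            raise ValueError(f"unknown drug_state {drug_state!r}")
        nat = ndtr(base)
        return nat * BETA_SCALE if parameter == "beta" else nat

    def natural_group_sd(self, parameter: str, drug_state: str = "placebo") -> float:
        """Posterior-median across-participant SD of the natural-scale
        parameter: the group-level SD point estimate used to set the ROPE
        for natural-scale contrasts."""
        nat = self.participant_natural(parameter, drug_state)
        return float(np.median(nat.std(axis=1, ddof=1)))

    def participant_effect(self, parameter: str) -> np.ndarray:
        """Per-draw atomoxetine-minus-placebo natural effect, (total_draws, P)."""
        return self.participant_natural(parameter, "atomoxetine") - self.participant_natural(
            parameter, "placebo"
        )

    # -- text I/O ----------------------------------------------------------
    def to_files(self, prefix) -> None:
        """Write long-format CSV (chain, iteration, parameter, value) plus a
        JSON metadata sidecar; the round trip is loss-free."""
        prefix = Path(prefix)
        rows = []
        for name, arr in self.draws.items():
            C, D = arr.shape[:2]
            chains = np.repeat(np.arange(C), D)
            iters = np.tile(np.arange(D), C)
            if arr.ndim == 2:
                rows.append(
                    pd.DataFrame(
                        {"chain": chains, "iteration": iters, "parameter": name,
                         "value": arr.reshape(-1)}
                    )
                )
            else:
                for j, pid in enumerate(self.participant_ids):
                    rows.append(
                        pd.DataFrame(
                            {"chain": chains, "iteration": iters,
                             "parameter": f"{name}[{pid}]",
                             "value": arr[:, :, j].reshape(-1)}
                        )
                    )
        pd.concat(rows, ignore_index=True).to_csv(
            prefix.with_suffix(".csv"), index=False, float_format="%.17g"
        )
        meta = {
            "design": self.design,
            "condition": self.condition,
            "participant_ids": [str(p) for p in self.participant_ids],
            **self.meta,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_files(cls, prefix) -> "PosteriorSamples":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
        pids = meta.pop("participant_ids")
        design = meta.pop("design")
        condition = meta.pop("condition")
        C = df["chain"].max() + 1
        D = df["iteration"].max() + 1
        draws: dict[str, np.ndarray] = {}
        vector_parts: dict[str, dict[str, np.ndarray]] = {}
        for name, sub in df.groupby("parameter", sort=False):
            arr = (
                sub.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(C, D)
            )
            if "[" in name:
                base, pid = name[:-1].split("[", 1)
                vector_parts.setdefault(base, {})[pid] = arr
            else:
                draws[name] = arr
        for base, parts in vector_parts.items():
            draws[base] = np.stack([parts[str(p)] for p in pids], axis=-1)
        return cls(
            draws=draws, design=design, condition=condition,
            participant_ids=pids, meta=meta,
        )
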