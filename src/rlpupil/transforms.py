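"""Probit-scale <-> natural-scale parameter transforms.

Unconstrained ("probit-scale") parameters are mapped to the bounded natural
scale with the standard normal CDF: ``alpha = Phi(alpha')`` in [0, 1] and
``beta = Phi(beta') * 10`` in [0, 10].  In a crossover design the placebo
session uses the participant value directly and the drug session adds a
participant-specific offset before the CDF.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from rlpupil.qlearning import BETA_BOUNDS

BETA_SCALE = BETA_BOUNDS[1]


def probit_to_alpha(alpha_probit):
    """``Phi(alpha')`` elementwise."""
    return ndtr(np.asarray(alpha_probit, dtype=float))


def probit_to_beta(beta_probit):
    """``Phi(beta') * 10`` elementwise."""
    return ndtr(np.asarray(beta_probit, dtype=float)) * BETA_SCALE


def transform_to_natural(
    alpha_probit, beta_probit, drug_state: str = "placebo",
    delta_alpha=0.0, delta_beta=0.0,
):
    """Map probit-scale values to natural-scale ``(alpha, beta)``.

    The ``atomoxetine`` path shifts by the offsets before the CDF; the
    ``placebo`` (or ``none``) path ignores them.
    """
    if drug_state == "atomoxetine":
        a = probit_to_alpha(np.asarray(alpha_probit) + np.asarray(delta_alpha))
        b = probit_to_beta(np.asarray(beta_probit) + np.asarray(delta_beta))
    elif drug_state in ("placebo", "none"):
        a = probit_to_alpha(alpha_probit)
        b = probit_to_beta(beta_probit)
    else:
        raise ValueError(f"unknown drug_state {drug_state!r}")
    return a, b
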