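"""Batched Q-learning choice log-likelihood and its gradient.

The kernel evolves a two-entry Q-table along each observed choice/outcome
sequence and accumulates the softmax log-likelihood together with its
partial derivatives with respect to the natural-scale learning rate and
inverse temperature (``dQ/dalpha`` is propagated through the delta-rule
recursion).  Sessions are padded to a common length and processed in one
call so the sampler's hot loop stays in compiled code.

numba is used when importable; the pure-Python fallback is identical code.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _session_loglik_grad(choices, outcomes, n, alpha, beta):
    q0 = 0.0
    q1 = 0.0
    dq0 = 0.0
    dq1 = 0.0
    ll = 0.0
    dla = 0.0
    dlb = 0.0
    for t in range(n):
        c = choices[t]
        r = outcomes[t]
        z0 = beta * q0
        z1 = beta * q1
        m = z0 if z0 > z1 else z1
        lse = m + math.log(math.exp(z0 - m) + math.exp(z1 - m))
        p0 = math.exp(z0 - lse)
        p1 = 1.0 - p0
        if c == 0:
            qc = q0
            dqc = dq0
        else:
            qc = q1
            dqc = dq1
        ll += beta * qc - lse
        dlb += qc - (p0 * q0 + p1 * q1)
        dla += beta * (dqc - (p0 * dq0 + p1 * dq1))
        if c == 0:
            dq0 = dq0 * (1.0 - alpha) + (r - q0)
            q0 = q0 + alpha * (r - q0)
        else:
            dq1 = dq1 * (1.0 - alpha) + (r - q1)
            q1 = q1 + alpha * (r - q1)
    return ll, dla, dlb


@njit(cache=True)
def _batch_loglik_grad(choices, outcomes, lengths, alpha, beta, ll, dla, dlb):
    for s in range(choices.shape[0]):
        l, ga, gb = _session_loglik_grad(
            choices[s], outcomes[s], lengths[s], alpha[s], beta[s]
        )
        ll[s] = l
        dla[s] = ga
        dlb[s] = gb


def batch_loglik_grad(
    choices: np.ndarray,
    outcomes: np.ndarray,
    lengths: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-session log-likelihood and gradients w.r.t. (alpha, beta).

    Parameters are natural-scale arrays, one entry per session; ``choices``
    and ``outcomes`` are (n_sessions, max_trials) padded arrays with valid
    prefixes of ``lengths`` trials.
    """
    S = choices.shape[0]
    ll = np.empty(S)
    dla = np.empty(S)
    dlb = np.empty(S)
    _batch_loglik_grad(
        np.ascontiguousarray(choices, dtype=np.int64),
        np.ascontiguousarray(outcomes, dtype=np.float64),
        np.ascontiguousarray(lengths, dtype=np.int64),
        np.ascontiguousarray(alpha, dtype=np.float64),
        np.ascontiguousarray(beta, dtype=np.float64),
        ll,
        dla,
        dlb,
    )
    return ll, dla, dlb
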