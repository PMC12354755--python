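"""Cluster-based permutation testing for paired pupil time series.

Per timepoint, a paired t-statistic is computed across participants on the
condition difference.  Contiguous runs of |t| above a threshold (default:
the two-sided 0.05 quantile of the t distribution with n-1 df) form
clusters separately per sign, each scored by its cluster mass statistic
(CMS, the sum of t values in the run).  The null distribution is the
maximum |CMS| per permutation under random within-participant sign flips,
giving family-wise control across time; p-values use the add-one rule and
can never fall below 1 / (1 + n_permutations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["Cluster", "ClusterResult", "cluster_permutation_test"]

DEFAULT_PERMUTATIONS = 2000


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    cluster_mass: float
    p_value: float
    direction: str  # 'positive' (A > B) or 'negative'


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    threshold: float
    t_values: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_json(self, path=None) -> str:
        payload = {
            "n_permutations": self.n_permutations,
            "threshold": self.threshold,
            "clusters": [asdict(c) for c in self.clusters],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t per column; all-zero columns yield t = 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t) & (mean == 0)] = 0.0
    return t


def _runs(mask: np.ndarray):
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _clusters_of(t: np.ndarray, threshold: float):
    """(start, stop, mass, direction) for suprathreshold runs, per sign."""
    out = []
    for sign, mask in (("positive", t > threshold), ("negative", t < -threshold)):
        for start, stop in _runs(mask):
            out.append((start, stop, float(t[start:stop].sum()), sign))
    return out


def _max_abs_mass(t: np.ndarray, threshold: float) -> float:
    best = 0.0
    for _, _, mass, _ in _clusters_of(t, threshold):
        best = max(best, abs(mass))
    return best


def cluster_permutation_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    rng_seed=None,
    threshold: float | None = None,
    times_ms: np.ndarray | None = None,
) -> ClusterResult:
    """Paired cluster-mass permutation test of condition A vs condition B.

    ``matrix_a``/``matrix_b`` hold one averaged time course per participant
    (rows paired by participant).  ``times_ms`` labels the columns; sample
    indices are used when omitted.
    """
    a = np.atleast_2d(np.asarray(matrix_a, dtype=float))
    b = np.atleast_2d(np.asarray(matrix_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition matrices must be paired (same shape)")
    n, n_t = a.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    if times_ms is None:
        times_ms = np.arange(n_t, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.shape != (n_t,):
        raise ValueError("times_ms length must match the time axis")
    if threshold is None:
        threshold = float(sps.t.ppf(0.975, n - 1))

    diff = a - b
    t_obs = _paired_t(diff)
    observed = _clusters_of(t_obs, threshold)

    rng = np.random.default_rng(rng_seed)
    # variance under sign flips only depends on the flipped mean:
    # sum(d^2) is flip-invariant, so t can be computed from S @ diff alone
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    sum_sq = np.sum(diff**2, axis=0)
    perm_means = signs @ diff / n
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_var = (sum_sq - n * perm_means**2) / (n - 1)
        perm_t = perm_means / np.sqrt(perm_var / n)
    perm_t[~np.isfinite(perm_t)] = 0.0

    null = np.fromiter(
        (_max_abs_mass(perm_t[k], threshold) for k in range(n_permutations)),
        dtype=float,
        count=n_permutations,
    )

    clusters = []
    for start, stop, mass, sign in observed:
        p = float((1 + np.sum(null >= abs(mass))) / (1 + n_permutations))
        clusters.append(
            Cluster(
                start_ms=float(times_ms[start]),
                end_ms=float(times_ms[stop - 1]),
                cluster_mass=mass,
                p_value=p,
                direction=sign,
            )
        )
    clusters.sort(key=lambda c: c.start_ms)
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_permutations,
        threshold=threshold,
        t_values=t_obs,
    )
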