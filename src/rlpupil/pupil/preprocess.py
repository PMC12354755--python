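"""Pupil preprocessing: blink interpolation, low-pass filtering, baseline
workflow, temporal derivative and within-session z-scoring.

Pipeline order (per session): blink runs shorter than 500 ms are linearly
interpolated with anchors 100 ms before/after the run; runs of 500 ms or
longer discard the trial.  Retained traces are low-pass filtered with a
second-order Butterworth (default cutoff 4 Hz, applied forward-backward so
the response is zero-phase — the cutoff is an assumption, configurable).
The per-trial baseline is the median of the final 500 ms of fixation;
trials with baselines outside mean +/- 2 SD within (participant, session)
are dropped (single pass, SD computed before any exclusion), and the
baseline median is subtracted from every retained sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from rlpupil.pupil.traces import PupilTrace

__all__ = [
    "FilterConfig",
    "PupilTrialMatrix",
    "interpolate_blinks",
    "preprocess_session",
    "preprocess_traces",
    "temporal_derivative",
    "zscore_within",
]

log = logging.getLogger(__name__)

MAX_BLINK_S = 0.5
ANCHOR_S = 0.1
BASELINE_S = 0.5
BASELINE_SD_LIMIT = 2.0
OUTCOME_WINDOW_S = 1.0

REASON_LONG_BLINK = "long-blink"
REASON_BASELINE_OUTLIER = "baseline-outlier"

INDEX_COLUMNS = ["participant_id", "drug_state", "condition", "trial"]


@dataclass(frozen=True)
class FilterConfig:
    cutoff_hz: float = 4.0  # assumption: not stated by the acquisition spec
    order: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class PupilTrialMatrix:
    """Aligned per-trial vectors plus exclusion bookkeeping.

    ``values`` rows share the time grid ``times`` (seconds relative to
    outcome onset).  ``index`` identifies each retained row; ``excluded``
    carries a machine-readable reason per dropped trial.
    """

    values: np.ndarray  # (n_trials, n_time)
    times: np.ndarray  # (n_time,)
    index: pd.DataFrame  # one row per retained trial
    baselines: np.ndarray  # (n_trials,) raw baseline medians
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=INDEX_COLUMNS + ["reason"])
    )
    dt: float = 0.002

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.index):
            raise ValueError("index/values length mismatch")

    def groups(self):
        """Iterate (key, row indices) by (participant, session)."""
        for key, sub in self.index.groupby(["participant_id", "drug_state"], sort=False):
            yield key, sub.index.to_numpy()

    def select(self, **conditions) -> "PupilTrialMatrix":
        mask = np.ones(len(self.index), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.index[col] == val).to_numpy()
        return PupilTrialMatrix(
            values=self.values[mask],
            times=self.times,
            index=self.index[mask].reset_index(drop=True),
            baselines=self.baselines[mask],
            excluded=self.excluded,
            dt=self.dt,
        )


def _missing_runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _anchor_median(diameter: np.ndarray, sl: slice) -> float | None:
    window = diameter[sl]
    window = window[~np.isnan(window)]
    return float(np.median(window)) if window.size else None


def interpolate_blinks(trace: PupilTrace) -> tuple[PupilTrace, bool]:
    """Linearly interpolate missing runs under 500 ms; flag longer runs.

    Returns ``(trace, discarded)``.  When any run is >= 500 ms the trial is
    flagged for discard and the samples are left untouched.  Interpolation
    draws a line between the medians of 100 ms anchor windows on either
    side of the run (one-sided at trace boundaries, logged).
    Non-missing samples are never altered.
    """
    missing = np.isnan(trace.diameter)
    if not missing.any():
        return trace, False
    fs = trace.fs
    max_len = int(round(MAX_BLINK_S * fs))
    anchor_len = max(1, int(round(ANCHOR_S * fs)))
    runs = _missing_runs(missing)
    if any((stop - start) >= max_len for start, stop in runs):
        return trace, True

    out = trace.diameter.copy()
    t = trace.time
    for start, stop in runs:
        left = _anchor_median(trace.diameter, slice(max(0, start - anchor_len), start))
        right = _anchor_median(
            trace.diameter, slice(stop, min(len(out), stop + anchor_len))
        )
        if left is None and right is None:
            raise ValueError("blink spans the whole trace; cannot anchor")
        if left is None or right is None:
            log.warning(
                "one-sided blink anchor at trace boundary (%s trial %s)",
                trace.participant_id,
                trace.trial,
            )
            fill = left if right is None else right
            out[start:stop] = fill
            continue
        # anchor points at the centres of the anchor windows
        t_left = t[max(0, start - anchor_len) : start].mean()
        t_right = t[stop : min(len(out), stop + anchor_len)].mean()
        slope = (right - left) / (t_right - t_left)
        out[start:stop] = left + slope * (t[start:stop] - t_left)
    return trace.with_diameter(out), False


def _lowpass(diameter: np.ndarray, fs: float, cfg: FilterConfig) -> np.ndarray:
    b, a = butter(cfg.order, cfg.cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, diameter)


def preprocess_session(
    traces: list[PupilTrace],
    filter_config: FilterConfig | None = None,
    outcome_window_s: float = OUTCOME_WINDOW_S,
) -> PupilTrialMatrix:
    """Filter, baseline-screen and baseline-correct blink-free traces.

    Expects blink handling to have been applied already (NaNs are an
    error).  Returns baseline-corrected outcome-phase samples aligned to
    outcome onset; the derivative and z-scoring are separate steps.
    """
    cfg = filter_config or FilterConfig()
    if not traces:
        raise ValueError("no traces")

    rows, baselines, keys = [], [], []
    n_win = None
    for tr in traces:
        if np.isnan(tr.diameter).any():
            raise ValueError("traces contain missing samples; run blink handling first")
        if tr.t_stimulus_on < BASELINE_S:
            raise ValueError("fixation phase shorter than the 500 ms baseline epoch")
        fs = tr.fs
        filtered = _lowpass(tr.diameter, fs, cfg)
        base_mask = (tr.time >= tr.t_stimulus_on - BASELINE_S) & (
            tr.time < tr.t_stimulus_on
        )
        baseline = float(np.median(filtered[base_mask]))
        start = int(np.searchsorted(tr.time, tr.t_outcome_on))
        if n_win is None:
            n_win = int(round(outcome_window_s * fs))
            dt = 1.0 / fs
        if start + n_win > len(filtered):
            raise ValueError("outcome phase shorter than the analysis window")
        rows.append(filtered[start : start + n_win] - baseline)
        baselines.append(baseline)
        keys.append(
            {
                "participant_id": tr.participant_id,
                "drug_state": tr.drug_state,
                "condition": tr.condition,
                "trial": tr.trial,
            }
        )

    index = pd.DataFrame(keys)
    values = np.asarray(rows)
    baselines = np.asarray(baselines)

    # single-pass +/- 2 SD baseline screen within (participant, session);
    # SD computed before exclusion, zero SD excludes nothing
    keep = np.ones(len(index), dtype=bool)
    for _, idx in index.groupby(["participant_id", "drug_state"], sort=False).groups.items():
        idx = np.asarray(idx)
        b = baselines[idx]
        sd = b.std(ddof=1) if len(b) > 1 else 0.0
        if sd > 0:
            mean = b.mean()
            keep[idx] = np.abs(b - mean) <= BASELINE_SD_LIMIT * sd

    excluded = index[~keep].copy()
    excluded["reason"] = REASON_BASELINE_OUTLIER

    return PupilTrialMatrix(
        values=values[keep],
        times=np.arange(n_win) * dt,
        index=index[keep].reset_index(drop=True),
        baselines=baselines[keep],
        excluded=excluded.reset_index(drop=True),
        dt=dt,
    )


def preprocess_traces(
    traces: list[PupilTrace], filter_config: FilterConfig | None = None
) -> PupilTrialMatrix:
    """Convenience pipeline: blink handling then session preprocessing; the
    two exclusion ledgers (long blinks, baseline outliers) are merged."""
    kept, discarded = [], []
    for tr in traces:
        fixed, discard = interpolate_blinks(tr)
        if discard:
            discarded.append(
                {
                    "participant_id": tr.participant_id,
                    "drug_state": tr.drug_state,
                    "condition": tr.condition,
                    "trial": tr.trial,
                    "reason": REASON_LONG_BLINK,
                }
            )
        else:
            kept.append(fixed)
    matrix = preprocess_session(kept, filter_config)
    if discarded:
        matrix.excluded = pd.concat(
            [pd.DataFrame(discarded), matrix.excluded], ignore_index=True
        )
    return matrix


def temporal_derivative(values: np.ndarray, dt: float | None = None) -> np.ndarray:
    """Signed difference between consecutive samples (not divided by dt).

    Output length is input length minus one along the last axis.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 2:
        raise ValueError("need at least two samples")
    return np.diff(values, axis=-1)


def derivative_matrix(matrix: PupilTrialMatrix) -> PupilTrialMatrix:
    """Apply the temporal derivative row-wise; the time grid loses its last
    point and the nominal dt is kept in metadata."""
    return PupilTrialMatrix(
        values=temporal_derivative(matrix.values),
        times=matrix.times[:-1],
        index=matrix.index.copy(),
        baselines=matrix.baselines,
        excluded=matrix.excluded,
        dt=matrix.dt,
    )


def zscore_within(matrix: PupilTrialMatrix) -> PupilTrialMatrix:
    """Z-score all samples within each (participant, session) group.

    Uses the n-1 SD convention; a zero-variance group is an error naming
    the offending group.
    """
    out = matrix.values.astype(float).copy()
    for key, idx in matrix.groups():
        block = out[idx]
        sd = block.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance within group {key}")
        out[idx] = (block - block.mean()) / sd
    return PupilTrialMatrix(
        values=out,
        times=matrix.times,
        index=matrix.index.copy(),
        baselines=matrix.baselines,
        excluded=matrix.excluded,
        dt=matrix.dt,
    )
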