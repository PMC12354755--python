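"""Pupil trace container and delimited-text I/O.

A trace is one trial's diameter time series at nominal 500 Hz, spanning
three contiguous phases: fixation, stimulus and outcome.  Missing samples
(blinks) are NaN in memory and empty fields on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["PupilTrace", "write_traces", "read_traces"]

PHASES = ("fixation", "stimulus", "outcome")


@dataclass
class PupilTrace:
    participant_id: str
    drug_state: str
    condition: str
    trial: int
    time: np.ndarray  # seconds, strictly increasing
    diameter: np.ndarray  # arbitrary units, NaN = missing
    t_stimulus_on: float  # fixation ends / stimulus starts
    t_outcome_on: float  # stimulus ends / outcome starts

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.shape != self.diameter.shape:
            raise ValueError("time and diameter must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("times must be strictly increasing")
        if not (0.0 < self.t_stimulus_on < self.t_outcome_on):
            raise ValueError("phase boundaries must satisfy 0 < stimulus_on < outcome_on")

    @property
    def fs(self) -> float:
        """Nominal sampling rate inferred from the time grid."""
        return 1.0 / float(np.median(np.diff(self.time)))

    def phase_of(self, t: np.ndarray) -> np.ndarray:
        out = np.full(np.shape(t), "fixation", dtype=object)
        t = np.asarray(t)
        out[t >= self.t_stimulus_on] = "stimulus"
        out[t >= self.t_outcome_on] = "outcome"
        return out

    def phase_mask(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.phase_of(self.time) == phase

    def with_diameter(self, diameter: np.ndarray) -> "PupilTrace":
        return replace(self, diameter=np.asarray(diameter, dtype=float))

    def key(self) -> tuple:
        return (self.participant_id, self.drug_state, self.condition, self.trial)


def write_traces(traces, path) -> None:
    """Write traces as long-format CSV (missing diameters as empty fields)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "drug_state": tr.drug_state,
                    "condition": tr.condition,
                    "trial": tr.trial,
                    "phase": tr.phase_of(tr.time),
                    "time_s": tr.time,
                    "diameter": tr.diameter,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")


def read_traces(path) -> list[PupilTrace]:
    """Read the CSV format written by :func:`write_traces`."""
    df = pd.read_csv(path)
    traces = []
    keys = ["participant_id", "drug_state", "condition", "trial"]
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy(float)
        phase = sub["phase"].to_numpy()
        stim = t[phase == "stimulus"]
        outc = t[phase == "outcome"]
        if len(stim) == 0 or len(outc) == 0:
            raise ValueError(f"trace {key} lacks stimulus or outcome samples")
        traces.append(
            PupilTrace(
                participant_id=str(key[0]),
                drug_state=str(key[1]),
                condition=str(key[2]),
                trial=int(key[3]),
                time=t,
                diameter=sub["diameter"].to_numpy(float),
                t_stimulus_on=float(stim[0]),
                t_outcome_on=float(outc[0]),
            )
        )
    return traces
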