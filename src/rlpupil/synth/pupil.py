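"""Synthetic pupil recordings with blinks, drug-dependent tonic baseline and
a biphasic (dilation then constriction) response locked to outcome onset."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from rlpupil.pupil.traces import PupilTrace

FIXATION_S = 3.5
OUTCOME_S = 2.5
STIMULUS_RANGE_S = (0.5, 2.5)  # response-terminated display, drawn uniform


def _default_baselines() -> dict:
    return {"placebo": 4000.0, "atomoxetine": 4400.0, "none": 4000.0}


@dataclass(frozen=True)
class SyntheticPupilSpec:
    sampling_rate: float = 500.0
    tonic_baseline: dict = field(default_factory=_default_baselines)
    phasic_amplitude: float = 120.0
    phasic_latency: float = 0.3  # s after outcome onset
    phasic_width: float = 0.08
    constriction_amplitude: float = 80.0
    constriction_latency: float = 0.7
    constriction_width: float = 0.15
    blink_rate: float = 0.1  # blinks per second
    blink_median_s: float = 0.15
    blink_sigma: float = 0.4  # lognormal shape
    long_blink_prob: float = 0.0  # chance a blink is forced > 500 ms
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("phasic_latency", "constriction_latency"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie within the 1000 ms outcome window")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticPupilSpec":
        return cls(**d)


def _gauss_bump(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - centre) / width) ** 2)


def _insert_blinks(
    diameter: np.ndarray, fs: float, spec: SyntheticPupilSpec, rng: np.random.Generator
) -> np.ndarray:
    duration_s = len(diameter) / fs
    n_blinks = rng.poisson(spec.blink_rate * duration_s)
    out = diameter.copy()
    for _ in range(n_blinks):
        if spec.long_blink_prob > 0 and rng.random() < spec.long_blink_prob:
            dur = 0.5 + rng.random() * 0.5
        else:
            dur = float(
                np.exp(np.log(spec.blink_median_s) + spec.blink_sigma * rng.standard_normal())
            )
        n = max(1, int(round(dur * fs)))
        start = rng.integers(0, max(1, len(out) - n))
        out[start : start + n] = np.nan
    return out


def generate_pupil_trace(
    spec: SyntheticPupilSpec,
    rng: np.random.Generator,
    participant_id: str = "sim",
    drug_state: str = "placebo",
    condition: str = "gain",
    trial: int = 0,
) -> PupilTrace:
    """Generate a single-trial trace: tonic baseline + biphasic outcome
    response + white noise + blink gaps."""
    fs = spec.sampling_rate
    stim_dur = float(rng.uniform(*STIMULUS_RANGE_S))
    if 1.0 / fs > min(FIXATION_S, stim_dur, OUTCOME_S):
        raise ValueError("sampling interval longer than the shortest phase")
    total = FIXATION_S + stim_dur + OUTCOME_S
    t = np.arange(0.0, total, 1.0 / fs)
    t_outcome = FIXATION_S + stim_dur

    base = spec.tonic_baseline.get(drug_state, spec.tonic_baseline.get("none", 0.0))
    signal = np.full_like(t, float(base))
    signal += spec.phasic_amplitude * _gauss_bump(
        t, t_outcome + spec.phasic_latency, spec.phasic_width
    )
    signal -= spec.constriction_amplitude * _gauss_bump(
        t, t_outcome + spec.constriction_latency, spec.constriction_width
    )
    if spec.noise_sd > 0:
        signal = signal + spec.noise_sd * rng.standard_normal(len(t))
    if spec.blink_rate > 0:
        signal = _insert_blinks(signal, fs, spec, rng)

    return PupilTrace(
        participant_id=participant_id,
        drug_state=drug_state,
        condition=condition,
        trial=trial,
        time=t,
        diameter=signal,
        t_stimulus_on=FIXATION_S,
        t_outcome_on=t_outcome,
    )


def generate_pupil_dataset(
    spec: SyntheticPupilSpec,
    schedule,
    rng_seed=None,
    participant_id: str = "sim",
    drug_state: str = "placebo",
) -> list[PupilTrace]:
    """One trace per trial of a task schedule, in presentation order.

    Trial numbering is per condition, matching the behavioural trial table.
    """
    rng = np.random.default_rng(rng_seed)
    counters = {c: 0 for c in schedule.conditions()}
    traces = []
    for condition in np.asarray(schedule.condition):
        traces.append(
            generate_pupil_trace(
                spec,
                rng,
                participant_id=participant_id,
                drug_state=drug_state,
                condition=str(condition),
                trial=counters[condition],
            )
        )
        counters[condition] += 1
    return traces
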