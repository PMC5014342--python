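"""Rhythmic vibrotactile cueing: baseline cadence, cue frequency and schedule.

Rhythmic somatosensory cueing entrains gait: short vibration pulses
delivered to the sole at a rate slightly above the walker's preferred
cadence improve step regularity.  The conventions implemented here are a
cue rate 10% above the baseline cadence (auditory-cueing literature
supports 90-125% of preferred cadence), 50 ms pulses, and activation only
when the current fall-risk score rises strictly above a reference score
(typically measured walking on concrete, the lowest-risk terrain).

The pulse train is an abstract on/off timeline — one pulse per step — that
a hardware driver would realise as a PWM burst on the vibration motor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InsufficientBaselineError, ParameterError
from .tug import GaitParams

PULSE_DURATION_S = 0.050
CADENCE_UPLIFT = 0.10


@dataclass
class CueSchedule:
    """A uniform vibrotactile pulse train.

    ``pulse_times`` are pulse onsets in seconds spaced ``60/frequency``;
    each pulse lasts ``pulse_duration`` (shorter than the inter-pulse
    interval).
    """

    pulse_times: np.ndarray
    pulse_duration: float
    frequency: float  # pulses/min

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.frequency <= 0:
            raise ParameterError("frequency must be positive")
        if self.pulse_duration >= 60.0 / self.frequency:
            raise ParameterError("pulse duration must be below the inter-pulse interval")

    def duty_pattern(self, sample_rate: float, duration: float) -> np.ndarray:
        """Boolean on/off timeline sampled at ``sample_rate`` for ``duration`` s."""
        t = np.arange(int(round(duration * sample_rate))) / sample_rate
        on = np.zeros(t.shape, dtype=bool)
        for onset in self.pulse_times:
            on |= (t >= onset) & (t < onset + self.pulse_duration)
        return on


def baseline_cadence(trials: Iterable[GaitParams]) -> float:
    """Preferred walking cadence: mean of per-trial mean cadences.

    At least two baseline (reference-terrain) trials are required.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientBaselineError(
            f"need at least 2 baseline trials, got {len(trials)}"
        )
    return float(np.mean([t.cadence_mean for t in trials]))


def cue_frequency(baseline: float, uplift: float = CADENCE_UPLIFT) -> float:
    """Cue rate in pulses/min: ``(1 + uplift)`` x baseline cadence."""
    if baseline <= 0:
        raise ParameterError("baseline cadence must be positive")
    return (1.0 + uplift) * baseline


def generate_schedule(
    frequency: float,
    duration: float,
    pulse_duration: float = PULSE_DURATION_S,
) -> CueSchedule:
    """Uniform pulse train at ``frequency`` pulses/min for ``duration`` s.

    Pulses start at t = 0, 60/f, 120/f, ... < duration.  Frequencies whose
    inter-pulse interval does not exceed the pulse duration are rejected.
    """
    if frequency <= 0 or duration <= 0:
        raise ParameterError("frequency and duration must be positive")
    interval = 60.0 / frequency
    if pulse_duration >= interval:
        raise ParameterError(
            f"{pulse_duration*1e3:.0f} ms pulses overlap at {frequency:g} pulses/min"
        )
    times = np.arange(0.0, duration, interval)
    times = times[times < duration]
    return CueSchedule(
        pulse_times=times, pulse_duration=pulse_duration, frequency=frequency
    )


def should_cue(current_risk: float, reference_risk: float) -> bool:
    """Activate cueing iff the current risk strictly exceeds the reference."""
    if current_risk < 0 or reference_risk < 0:
        raise ParameterError("risk scores must be non-negative")
    return current_risk > reference_risk
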