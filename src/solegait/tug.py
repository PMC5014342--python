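"""Timed Up and Go (TUG) segmentation, gait parameters and fall-risk scoring.

The TUG test — rise from a chair, walk 3 m, turn, walk back, sit down — is
segmented from the insole's load (FSR) and acceleration channels alone:

* trial start/end from sustained crossings of a standing-load threshold on
  the total FSR channel;
* steps as peaks of the low-passed, mean-removed acceleration magnitude,
  cross-checked against FSR burst counts;
* the turn as the run of unusually long step intervals nearest the temporal
  midpoint of the walking portion.

Gait parameters follow the common insole conventions: instantaneous
cadence ``60 / step interval`` (steps/min); stride length from the mean
rectified stride acceleration,

.. math::  SL = 0.98 \\cdot \\left(\\tfrac{1}{N}\\sum_{i=1}^{N} |a_i|\\right)^{1/3},

with :math:`a_i` the mean-removed acceleration samples of the stride; and
walking speed as accumulated stride length over walking time.

Gait variability is summarised by the coefficient of variation
``CV = 100 * sigma / mean`` of each parameter series, and the fall-risk
index combines them as ``Risk = alpha * (CV_cad + CV_SL)`` with ``alpha``
inversely proportional to the (dimensionless) walking-speed value: slow,
irregular gait scores high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks

from .errors import (
    InsufficientStepsError,
    ParameterError,
    SegmentationError,
    UndefinedResultError,
)
from .sensor_io import Recording

logger = logging.getLogger(__name__)

#: TUG-time mobility categories (seconds): below the first bound is freely
#: mobile, above the second is associated with increased fall risk.
TUG_NORMAL_S = 10.0
TUG_INCREASED_RISK_S = 16.0


@dataclass
class TUGPhases:
    """Phase boundaries of one TUG trial, in recording seconds."""

    t_start: float          # beginning of sit-to-stand
    t_stand_end: float      # end of sit-to-stand = first step
    t_turn_start: float
    t_turn_end: float
    t_walkback_end: float   # last step = beginning of stand-to-sit
    t_end: float            # end of stand-to-sit

    def __post_init__(self) -> None:
        seq = (self.t_start, self.t_stand_end, self.t_turn_start,
               self.t_turn_end, self.t_walkback_end, self.t_end)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ParameterError("phase boundaries must be strictly increasing")

    @property
    def tug_time(self) -> float:
        return self.t_end - self.t_start


@dataclass
class StepEvents:
    """Detected step times (s) and which sensor stream produced them."""

    times: np.ndarray
    source: str  # {"accel", "fsr", "fused"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("step times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GaitParams:
    """Cadence, stride lengths and speed for one walking bout."""

    cadence_mean: float           # steps/min
    inst_cadence: np.ndarray      # steps/min per step interval
    stride_lengths: np.ndarray    # m per stride
    speed: float                  # m/s


@dataclass
class RiskScore:
    """Risk-of-falling index and its components (all CVs in percent)."""

    cv_cadence: float
    cv_stride: float
    alpha: float
    risk: float


# -- segmentation --------------------------------------------------------------

def _sustained_crossings(
    above: np.ndarray, min_run: int
) -> tuple[int | None, int | None]:
    """First index opening a >=min_run run of True, and the index just past
    the last such run's end (i.e. where load is finally lost)."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None, None
    # split into contiguous runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [idx.size - 1]])
    first = last = None
    for s, e in zip(run_starts, run_ends):
        if idx[e] - idx[s] + 1 >= min_run:
            if first is None:
                first = int(idx[s])
            last = int(idx[e])
    return first, last


def segment_tug(
    rec: Recording,
    load_frac: float = 0.5,
    sustain_s: float = 0.5,
    turn_factor: float = 1.3,
    step_kwargs: dict | None = None,
) -> TUGPhases:
    """Segment one TUG trial into its phases from the insole streams.

    The standing-load threshold is ``load_frac`` x the median *loaded* FSR
    value (median of samples in the upper half of the channel's range).
    Trial start/end are the first/last crossings sustained for at least
    ``sustain_s``.  The turn is the contiguous run of step intervals,
    nearest the temporal midpoint of the walking portion, exceeding
    ``turn_factor`` x the median step interval.
    """
    fsr = rec.total_fsr()
    peak = float(np.max(fsr))
    if peak <= 0:
        raise SegmentationError("flat FSR channel: no load plateau found")
    loaded = fsr[fsr >= 0.5 * peak]
    threshold = load_frac * float(np.median(loaded))
    min_run = max(int(round(sustain_s * rec.sample_rate)), 1)
    first, last = _sustained_crossings(fsr > threshold, min_run)
    if first is None:
        raise SegmentationError(
            f"no sustained load above threshold {threshold:.3g} for {sustain_s} s"
        )
    t_start = float(rec.t[first])
    t_end = float(rec.t[last])

    # steps inside the loaded portion
    steps = _accel_step_times(
        rec, t_start, t_end, **(step_kwargs or {})
    )
    if len(steps) < 3:
        raise SegmentationError("too few steps to segment the walking phases")

    intervals = np.diff(steps)
    median_iv = float(np.median(intervals))
    long_iv = np.flatnonzero(intervals > turn_factor * median_iv)
    if long_iv.size == 0:
        raise SegmentationError("no turning interval found (no slowed steps)")
    # contiguous runs of long intervals; pick the run nearest the walking midpoint
    breaks = np.flatnonzero(np.diff(long_iv) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [long_iv.size - 1]])
    midpoint = (steps[0] + steps[-1]) / 2.0
    best = min(
        zip(run_starts, run_ends),
        key=lambda se: abs(
            (steps[long_iv[se[0]]] + steps[long_iv[se[1]] + 1]) / 2.0 - midpoint
        ),
    )
    t_turn_start = float(steps[long_iv[best[0]]])
    t_turn_end = float(steps[long_iv[best[1]] + 1])

    return TUGPhases(
        t_start=t_start,
        t_stand_end=float(steps[0]),
        t_turn_start=t_turn_start,
        t_turn_end=t_turn_end,
        t_walkback_end=float(steps[-1]),
        t_end=t_end,
    )


# -- step detection -------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= nyq:
        return x
    b, a = butter(4, cutoff / nyq)
    return filtfilt(b, a, x)


def _accel_step_times(
    rec: Recording,
    t_lo: float,
    t_hi: float,
    min_interval_s: float = 0.3,
    prominence_frac: float = 0.5,
    lowpass_hz: float = 10.0,
) -> np.ndarray:
    mag = rec.accel_magnitude()
    mag = mag - np.mean(mag)
    mag = _lowpass(mag, rec.sample_rate, lowpass_hz)
    # search a padded window so peaks sitting exactly on the bounds (the
    # first and last steps define t_lo/t_hi downstream) are still local maxima
    pad = min_interval_s
    sel = (rec.t >= t_lo - pad) & (rec.t <= t_hi + pad)
    seg = mag[sel]
    if seg.size == 0 or np.std(seg) == 0:
        return np.array([])
    peaks, _ = find_peaks(
        seg,
        distance=max(int(round(min_interval_s * rec.sample_rate)), 1),
        prominence=prominence_frac * float(np.std(seg)),
    )
    times = rec.t[sel][peaks]
    eps = 0.5 / rec.sample_rate
    return times[(times >= t_lo - eps) & (times <= t_hi + eps)]


def _fsr_burst_times(rec: Recording, t_lo: float, t_hi: float,
                     min_interval_s: float = 0.3) -> np.ndarray:
    """Step times from the per-step modulation of the heel FSR channel."""
    fsr = rec.heel_fsr().astype(float)
    span = float(np.max(fsr) - np.min(fsr))
    if span <= 0:
        return np.array([])
    # median-filter detrending removes the slow load envelope but keeps
    # sub-second step bumps at full height
    win = max(int(round(1.0 * rec.sample_rate)) | 1, 3)
    fsr = fsr - median_filter(fsr, size=win, mode="nearest")
    pad = min_interval_s
    sel = (rec.t >= t_lo - pad) & (rec.t <= t_hi + pad)
    seg = fsr[sel]
    if seg.size == 0 or np.std(seg) < 1e-6 * span:
        return np.array([])
    peaks, _ = find_peaks(
        seg,
        distance=max(int(round(min_interval_s * rec.sample_rate)), 1),
        prominence=0.5 * float(np.std(seg)),
    )
    times = rec.t[sel][peaks]
    # stance load peaks lag the impact peak; a burst within half a step
    # interval of the bounds belongs to the boundary step
    slack = 0.5 * min_interval_s
    return times[(times >= t_lo - slack) & (times <= t_hi + slack)]


def detect_steps(
    rec: Recording,
    phases: TUGPhases,
    min_interval_s: float = 0.3,
    prominence_frac: float = 0.5,
    lowpass_hz: float = 10.0,
    fsr_tolerance: float = 0.2,
) -> StepEvents:
    """Detect step events in the walking portion of a TUG trial.

    Steps are peaks of the mean-removed, 10 Hz low-passed acceleration
    magnitude within ``[t_stand_end, t_walkback_end]``, at least
    ``min_interval_s`` apart, with prominence >= ``prominence_frac`` x the
    segment standard deviation.  When the accelerometer count disagrees with
    the FSR burst count by more than ``fsr_tolerance`` of the latter, the
    FSR-derived steps are used instead (and a warning logged).
    """
    accel_times = _accel_step_times(
        rec, phases.t_stand_end, phases.t_walkback_end,
        min_interval_s=min_interval_s,
        prominence_frac=prominence_frac,
        lowpass_hz=lowpass_hz,
    )
    fsr_times = _fsr_burst_times(
        rec, phases.t_stand_end, phases.t_walkback_end, min_interval_s
    )
    source, times = "accel", accel_times
    if len(fsr_times) > 0 and abs(len(accel_times) - len(fsr_times)) > fsr_tolerance * len(fsr_times):
        logger.warning(
            "accelerometer step count %d disagrees with FSR burst count %d; "
            "falling back to FSR steps",
            len(accel_times), len(fsr_times),
        )
        source, times = "fsr", fsr_times
    if len(times) < 2:
        raise InsufficientStepsError(
            f"only {len(times)} steps detected in the walking portion"
        )
    return StepEvents(times=times, source=source)


# -- gait parameters -------------------------------------------------------------

def stride_length(accel_segment: np.ndarray) -> float:
    """Stride length from the mean rectified stride acceleration.

    ``SL = 0.98 * (sum(|a_i|) / N)^(1/3)`` with the segment mean removed
    first; a zero segment gives 0 m.
    """
    a = np.asarray(accel_segment, dtype=float)
    if a.size == 0:
        raise ParameterError("empty stride segment")
    a = a - np.mean(a)
    return 0.98 * float(np.mean(np.abs(a))) ** (1.0 / 3.0)


def _stride_bounds(times: np.ndarray, single_foot: bool) -> list[tuple[float, float]]:
    """Stride spans from step times: consecutive pairs of steps (both feet
    registering), or doubled single intervals with one instrumented foot."""
    if single_foot:
        return [(times[k], times[k + 1]) for k in range(len(times) - 1)]
    return [
        (times[2 * k], times[2 * k + 2]) for k in range((len(times) - 1) // 2)
    ]


def gait_params(
    steps: StepEvents,
    rec: Recording,
    phases: TUGPhases,
    single_foot: bool = False,
) -> GaitParams:
    """Cadence, stride lengths and walking speed from detected steps.

    Step intervals overlapping the turning phase are excluded from the
    cadence and stride statistics: turning intervals exceed the walking
    median by construction and would conflate turning style with gait
    variability.  Walking speed is accumulated stride length over the
    walking time (stand-end to walk-back-end).
    """
    if len(steps) < 3:
        raise InsufficientStepsError("need at least 3 steps for gait parameters")
    times = steps.times

    def in_turn(a: float, b: float) -> bool:
        return a < phases.t_turn_end and b > phases.t_turn_start

    intervals = [
        (t0, t1) for t0, t1 in zip(times[:-1], times[1:]) if not in_turn(t0, t1)
    ]
    if len(intervals) < 2:
        raise InsufficientStepsError("too few non-turning step intervals")
    inst_cadence = np.array([60.0 / (b - a) for a, b in intervals])

    mag = rec.accel_magnitude()
    strides = [
        (a, b) for a, b in _stride_bounds(times, single_foot) if not in_turn(a, b)
    ]
    sls = []
    for a, b in strides:
        sel = (rec.t >= a) & (rec.t < b)
        if np.count_nonzero(sel) > 0:
            sls.append(stride_length(mag[sel]))
    if not sls:
        raise InsufficientStepsError("no usable strides")
    stride_lengths = np.array(sls)
    walking_time = phases.t_walkback_end - phases.t_stand_end
    speed = float(np.sum(stride_lengths)) / walking_time
    return GaitParams(
        cadence_mean=float(np.mean(inst_cadence)),
        inst_cadence=inst_cadence,
        stride_lengths=stride_lengths,
        speed=speed,
    )


# -- variability and risk ---------------------------------------------------------

def coefficient_of_variation(series: np.ndarray) -> float:
    """CV in percent: 100 x sample standard deviation (n-1) / mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ParameterError("CV needs at least 2 values")
    mean = float(np.mean(x))
    if mean == 0:
        raise UndefinedResultError("CV undefined for zero-mean series")
    return 100.0 * float(np.std(x, ddof=1)) / mean


def risk_of_falling(gp: GaitParams, alpha_c: float = 1.0) -> RiskScore:
    """Risk index: ``alpha * (CV_cad + CV_SL)`` with ``alpha = alpha_c / speed``.

    Both CVs are in percent, so the risk is a percentage-scaled score; the
    inverse-speed weighting raises the score for slow walkers at equal
    variability.
    """
    if gp.speed <= 0:
        raise UndefinedResultError("risk undefined at zero walking speed")
    cv_cad = coefficient_of_variation(gp.inst_cadence)
    cv_sl = coefficient_of_variation(gp.stride_lengths)
    alpha = alpha_c / gp.speed
    return RiskScore(
        cv_cadence=cv_cad,
        cv_stride=cv_sl,
        alpha=alpha,
        risk=alpha * (cv_cad + cv_sl),
    )


def categorize_tug(phases: TUGPhases) -> str:
    """Mobility category from total TUG time.

    Under 10 s is ``normal`` mobility; over 16 s is associated with
    ``increased_risk`` of falling; in between (bounds included) is
    ``intermediate``.
    """
    t = phases.tug_time
    if t < TUG_NORMAL_S:
        return "normal"
    if t > TUG_INCREASED_RISK_S:
        return "increased_risk"
    return "intermediate"
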