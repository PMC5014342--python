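"""Heel-strike windowing and the four-step acceleration preprocessing chain.

Each heel strike excites the ground like an impulse; the vertical
acceleration recorded during heel contact approximates the terrain's impulse
response.  Strike windows are gated by the heel FSR channel with hysteresis
thresholding, then the vertical-axis segment goes through a fixed chain:

1. mean removal (so zero-padding does not create a step edge),
2. zero-padding of the tail to the next power of two (for the FFT),
3. multiplication by a Hamming window of the padded length,
4. Savitzky-Golay polynomial smoothing.

The chain is linear, so spectra of preprocessed windows scale with impact
amplitude but keep their shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.signal.windows import hamming

from .errors import ParameterError
from .sensor_io import Recording


@dataclass
class StrikeWindow:
    """One heel-strike acceleration segment, raw.

    ``[start_index, end_index)`` indexes into the source recording;
    ``signal`` is the raw vertical acceleration segment in m/s².
    """

    start_index: int
    end_index: int
    signal: np.ndarray
    soil_label: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.end_index <= self.start_index:
            raise ParameterError("end_index must exceed start_index")
        if len(self.signal) != self.end_index - self.start_index:
            raise ParameterError("signal length must equal end_index - start_index")


@dataclass
class ProcessedWindow:
    """A strike window after the preprocessing chain.

    ``padded_length`` is the power of two the window was padded to; the
    output ``signal`` has exactly that length.
    """

    signal: np.ndarray
    padded_length: int
    window_applied: bool
    filter_params: tuple[int, int]  # (polynomial order, window length)

    def __post_init__(self) -> None:
        n = self.padded_length
        if n <= 0 or (n & (n - 1)) != 0:
            raise ParameterError("padded_length must be a power of two")
        if len(self.signal) != n:
            raise ParameterError("signal length must equal padded_length")


def next_pow2(n: int) -> int:
    """Smallest power of two >= n (>= 1)."""
    return 1 << max(int(n) - 1, 0).bit_length()


def detect_strikes(
    rec: Recording,
    onset_frac: float = 0.3,
    release_frac: float = 0.1,
    max_window_ms: float | None = 250.0,
) -> list[StrikeWindow]:
    """Detect heel-strike windows from the heel FSR channel.

    A window opens when the heel FSR rises above ``onset_frac`` x the
    channel maximum over the whole recording and closes when it falls below
    ``release_frac`` x max (hysteresis, so noise between the two thresholds
    does not split a contact).  The vertical acceleration between the
    crossings is extracted; ``max_window_ms`` caps each window to the impact
    transient.  A flat or all-zero FSR channel yields an empty list.
    """
    if not (0.0 < release_frac < onset_frac < 1.0):
        raise ParameterError("need 0 < release_frac < onset_frac < 1")
    fsr = rec.heel_fsr()
    peak = float(np.max(fsr))
    if peak <= 0:
        return []
    hi = onset_frac * peak
    lo = release_frac * peak

    max_len = None
    if max_window_ms is not None:
        max_len = max(int(round(max_window_ms / 1000.0 * rec.sample_rate)), 1)

    label = rec.meta.get("soil")
    windows: list[StrikeWindow] = []
    in_contact = False
    start = 0
    for i, value in enumerate(fsr):
        if not in_contact and value > hi:
            in_contact = True
            start = i
        elif in_contact and value < lo:
            windows.append(_make_window(rec, start, i, max_len, label))
            in_contact = False
    if in_contact:
        windows.append(_make_window(rec, start, len(fsr), max_len, label))
    return windows


def _make_window(
    rec: Recording, start: int, end: int, max_len: int | None, label: str | None
) -> StrikeWindow:
    if max_len is not None:
        end = min(end, start + max_len)
    return StrikeWindow(
        start_index=start,
        end_index=end,
        signal=rec.accel_z[start:end],
        soil_label=label,
    )


def preprocess_strike(
    w: StrikeWindow, sg_order: int = 3, sg_window: int = 11
) -> ProcessedWindow:
    """Apply the four-step preprocessing chain to one strike window.

    Order: mean removal -> zero-pad tail to next power of two -> Hamming
    window of the padded length -> Savitzky-Golay smoothing with
    ``(sg_order, sg_window)``.  Output length equals the padded length.
    """
    n_raw = len(w.signal)
    if n_raw == 0:
        raise ParameterError("empty strike window")
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ParameterError("sg_window must be odd and exceed sg_order")
    padded = next_pow2(n_raw)
    if sg_window > padded:
        raise ParameterError("sg_window exceeds padded window length")

    x = w.signal - np.mean(w.signal)
    x = np.concatenate([x, np.zeros(padded - n_raw)])
    x = x * hamming(padded, sym=True)
    x = savgol_filter(x, window_length=sg_window, polyorder=sg_order)
    return ProcessedWindow(
        signal=x,
        padded_length=padded,
        window_applied=True,
        filter_params=(sg_order, sg_window),
    )
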