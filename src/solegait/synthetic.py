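"""Synthetic insole signals with known ground truth.

No public dataset of insole heel-strike vibrations or instrumented TUG
trials exists, so this module generates both study regimes from first
principles:

* **Soil strikes** (~1 kHz): a heel strike excites granular terrain like an
  impulse; the vertical acceleration is modelled as a sum of exponentially
  damped sinusoids at terrain-specific resonances plus white "grain" noise,
  gated by a half-sine contact envelope, with the ring onset placed inside
  the contact window (the FSR closes before peak impact).  Hard terrain
  (concrete) rings at a single high frequency with little damping;
  deformable granular terrain (sand, stone dust) responds low and broad,
  with per-strike resonance wander and optionally phase-dispersed
  (reverberant) energy — which is what scatters its centroid off a tight
  cluster.

* **TUG trials** (100 Hz): total plantar load ramps up at sit-to-stand,
  stays high through walking and the turn, and ramps down at stand-to-sit;
  each step is a fixed-shape acceleration pulse riding on gravity plus a
  load bump on the FSR channel.  Step intervals are drawn around the
  nominal cadence with a chosen coefficient of variation; per-stride pulse
  amplitudes are calibrated by inverting the stride-length relation
  ``SL = 0.98 * (mean |a|)^(1/3)`` so the generated trial carries known
  stride lengths.  Step times are snapped to the sample grid so nominal
  zero variability stays (near-)zero after detection.

Every generator is a pure function of (profile, rate, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .heelstrike import StrikeWindow
from .sensor_io import Recording
from .tug import TUGPhases

GRAVITY = 9.81  # m/s², carried on the vertical axis of TUG accel signals

# fixed per-step pulse: one full sine cycle, so it is zero-mean
_STEP_PULSE_S = 0.30
_STEP_PEAK_OFFSET_S = _STEP_PULSE_S / 4.0  # positive lobe peak
_FSR_SIT = 2.0
_FSR_LOAD = 100.0
_FSR_STEP_BUMP = 30.0

# fraction of the strike window elapsed before peak heel impact
_IMPACT_ONSET_FRAC = 0.3


@dataclass
class SoilProfile:
    """Damped-resonance model of one terrain's heel-strike response.

    ``grain_noise_level`` sets the standard deviation of the grain noise
    relative to the unit-scale ring.  ``phase`` chooses the temporal
    structure of the response: ``"coherent"`` keeps the impact transient
    (ring plus noise, front-loaded and impulsive), while ``"diffuse"``
    randomises the spectral phase of the very same waveform — emulating
    grain reverberation that smears the impact energy across the contact.
    The two variants share the magnitude spectrum exactly, so they differ
    in time-domain statistics (e.g. kurtosis) but not in spectral ones.
    """

    name: str
    resonance_freqs: list[float]          # Hz, all below Nyquist of the target rate
    damping_ratios: list[float]           # per resonance, in (0, 1)
    grain_noise_level: float = 0.0        # noise std relative to the ring
    impact_amplitude: float = 20.0        # m/s² peak scale
    duration_ms: float = 180.0
    phase: str = "coherent"               # {"coherent", "diffuse"}
    freq_jitter_hz: float = 0.0           # per-strike resonance wander (deformable soil)

    def __post_init__(self) -> None:
        if len(self.resonance_freqs) != len(self.damping_ratios):
            raise ParameterError("one damping ratio per resonance required")
        if any(not (0.0 < z < 1.0) for z in self.damping_ratios):
            raise ParameterError("damping ratios must lie in (0, 1)")
        if self.grain_noise_level < 0 or self.impact_amplitude < 0:
            raise ParameterError("noise level and amplitude must be >= 0")
        if self.phase not in ("coherent", "diffuse"):
            raise ParameterError("phase must be 'coherent' or 'diffuse'")
        if self.freq_jitter_hz < 0:
            raise ParameterError("freq_jitter_hz must be >= 0")


@dataclass
class GaitProfile:
    """Statistical structure of one synthetic TUG trial."""

    n_strides: int = 6
    cadence_mean: float = 120.0       # steps/min
    cadence_cv_nominal: float = 2.0   # %
    stride_len_mean: float = 1.0      # m
    stride_cv_nominal: float = 2.0    # %
    phase_durations: tuple[float, float, float] = (1.2, 1.2, 1.2)
    # (sit-to-stand, turn, stand-to-sit) in seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ParameterError("need at least 2 strides")
        if min(self.cadence_mean, self.stride_len_mean) <= 0:
            raise ParameterError("cadence and stride length must be positive")
        if min(self.cadence_cv_nominal, self.stride_cv_nominal) < 0:
            raise ParameterError("nominal CVs must be >= 0")
        if min(self.phase_durations) <= 0:
            raise ParameterError("phase durations must be positive")


@dataclass
class TUGGroundTruth:
    """What the generator actually put into a synthetic TUG recording."""

    phases: TUGPhases
    step_times: np.ndarray
    stride_lengths: np.ndarray
    cadence_mean: float
    cadence_cv_nominal: float
    stride_cv_nominal: float
    meta: dict = field(default_factory=dict)


# -- soil strikes --------------------------------------------------------------


def _strike_waveform(p: SoilProfile, rate: float, rng: np.random.Generator) -> np.ndarray:
    nyquist = rate / 2.0
    if any(f >= nyquist for f in p.resonance_freqs):
        raise ParameterError("resonance frequency at or above Nyquist")
    n = max(int(round(p.duration_ms / 1000.0 * rate)), 2)
    t = np.arange(n) / rate
    # the FSR contact opens before peak impact: the ring starts inside the
    # window, where downstream tapering windows have appreciable gain
    t0 = _IMPACT_ONSET_FRAC * t[-1]
    tau = np.clip(t - t0, 0.0, None)
    active = t >= t0
    core = np.zeros(n)
    for f, zeta in zip(p.resonance_freqs, p.damping_ratios):
        if p.freq_jitter_hz > 0:
            # deformable soil: the effective stiffness wanders strike to strike
            f = float(np.clip(f + p.freq_jitter_hz * rng.standard_normal(),
                              1.0, 0.95 * nyquist))
        omega = 2.0 * np.pi * f
        core += active * np.exp(-zeta * omega * tau) * np.sin(omega * tau)
    core /= len(p.resonance_freqs)
    noise = p.grain_noise_level * rng.standard_normal(n)
    envelope = np.sin(np.pi * t / t[-1])
    wave = p.impact_amplitude * (core + noise) * envelope
    if p.phase == "diffuse":
        # randomise spectral phase: same magnitude spectrum, energy smeared
        # through the window (grain reverberation instead of a crisp transient)
        spec = np.fft.rfft(wave)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape)
        phi[0] = 0.0
        if n % 2 == 0:
            phi[-1] = 0.0
        wave = np.fft.irfft(np.abs(spec) * np.exp(1j * phi), n)
    return wave


def simulate_strike(p: SoilProfile, rate: float = 1000.0, seed: int = 0) -> StrikeWindow:
    """One synthetic heel-strike acceleration window for terrain ``p``."""
    rng = np.random.default_rng(seed)
    wave = _strike_waveform(p, rate, rng)
    return StrikeWindow(
        start_index=0, end_index=len(wave), signal=wave, soil_label=p.name
    )


def simulate_soil_dataset(
    profiles: list[SoilProfile],
    n_per_class: int = 13,
    rate: float = 1000.0,
    seed: int = 0,
    gap_ms: float = 300.0,
) -> list[Recording]:
    """One labelled Recording per terrain, each with ``n_per_class`` strikes.

    Strikes are embedded in a quiet trace with a rectangular heel-FSR burst
    spanning each contact, so the full heel-strike detection chain can run
    on the output.  ``meta['soil']`` carries the ground-truth label.
    """
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate profile names")
    seeds = np.random.SeedSequence(seed).spawn(len(profiles))
    recordings = []
    for p, ss in zip(profiles, seeds):
        rng = np.random.default_rng(ss)
        gap = max(int(round(gap_ms / 1000.0 * rate)), 1)
        pieces_z, pieces_f = [np.zeros(gap)], [np.zeros(gap)]
        for _ in range(n_per_class):
            wave = _strike_waveform(p, rate, rng)
            pieces_z.append(wave)
            pieces_f.append(np.full(len(wave), _FSR_LOAD))
            pieces_z.append(np.zeros(gap))
            pieces_f.append(np.zeros(gap))
        accel_z = np.concatenate(pieces_z)
        fsr = np.concatenate(pieces_f)
        n = len(accel_z)
        recordings.append(
            Recording(
                sample_rate=rate,
                t=np.arange(n) / rate,
                accel_x=np.zeros(n),
                accel_y=np.zeros(n),
                accel_z=accel_z,
                fsr={"heel": fsr},
                meta={"soil": p.name, "n_strikes": n_per_class},
            )
        )
    return recordings


def default_soil_profiles() -> list[SoilProfile]:
    """The shipped six-terrain profile library (1 kHz regime).

    The four low-noise terrains are separated by resonance frequency
    (>= 40 Hz apart, within the passband of the default preprocessing
    chain): harder surfaces ring higher with less damping.  The two
    deformable granular terrains are spectral twins — the same heavily
    damped resonance with per-strike frequency wander — that differ only in
    temporal structure: stone dust keeps the crisp fracture transient
    (``phase="coherent"``), sand smears the same energy across the contact
    as diffuse grain reverberation (``phase="diffuse"``).  Their spectral
    centroids (Sx, Sy) are therefore statistically coincident while
    time-domain kurtosis separates them sharply, so centroid-only
    classification necessarily confuses them — the failure mode deformable
    terrain induces in real strikes — while the weighted feature level does
    not.
    """
    granular = dict(grain_noise_level=0.05, impact_amplitude=60.0,
                    duration_ms=200.0, freq_jitter_hz=5.0)
    return [
        SoilProfile("concrete", [145.0], [0.02], 0.02, 10.0, 150.0),
        SoilProfile("parquet", [105.0], [0.03], 0.02, 9.0, 160.0),
        SoilProfile("carpet", [65.0], [0.06], 0.03, 7.0, 180.0),
        SoilProfile("carpet_foam", [25.0], [0.10], 0.03, 5.0, 200.0),
        SoilProfile("sand", [85.0], [0.20], phase="diffuse", **granular),
        SoilProfile("stone_dust", [85.0], [0.20], phase="coherent", **granular),
    ]


# -- TUG trials ---------------------------------------------------------------


def _pulse(n: int) -> np.ndarray:
    """One full sine cycle over n samples (zero-mean step pulse shape)."""
    return np.sin(2.0 * np.pi * np.arange(n) / n)


def simulate_tug(
    g: GaitProfile,
    soil: SoilProfile | None = None,
    rate: float = 100.0,
    seed: int = 0,
) -> tuple[Recording, TUGGroundTruth]:
    """One synthetic TUG trial plus its ground truth.

    ``soil`` optionally adds terrain-dependent acceleration noise
    (``0.3 * grain_noise_level`` m/s² white) and labels the recording.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    d_s2s, d_turn, d_s2sit = g.phase_durations

    n_steps = 2 * g.n_strides + 1
    mean_iv = 60.0 / g.cadence_mean
    sd_iv = g.cadence_cv_nominal / 100.0 * mean_iv
    intervals = rng.normal(mean_iv, sd_iv, size=n_steps - 1)
    intervals = np.clip(intervals, 0.35, None)  # keep steps detectable/ordered

    sit_pre = 1.5
    t_ramp_up = sit_pre
    t_first_step = t_ramp_up + d_s2s + 0.3
    # outbound steps 0..n_strides, turn gap, inbound steps
    step_times = [t_first_step]
    for k, iv in enumerate(intervals):
        gap = d_turn if k == g.n_strides else iv
        step_times.append(step_times[-1] + gap)
    # snap to the sample grid so zero nominal variability survives detection
    step_times = np.round(np.array(step_times) / dt) * dt

    t_last_step = step_times[-1]
    t_ramp_down = t_last_step + _STEP_PULSE_S + 0.5
    total = t_ramp_down + d_s2sit + 1.5
    n = int(round(total * rate))
    t = np.arange(n) / rate

    # ---- FSR: load envelope + per-step bumps
    fsr = np.full(n, _FSR_SIT)
    ramp_up = (t >= t_ramp_up) & (t < t_ramp_up + d_s2s)
    fsr[ramp_up] = _FSR_SIT + (_FSR_LOAD - _FSR_SIT) * (t[ramp_up] - t_ramp_up) / d_s2s
    loaded = (t >= t_ramp_up + d_s2s) & (t < t_ramp_down)
    fsr[loaded] = _FSR_LOAD
    ramp_down = (t >= t_ramp_down) & (t < t_ramp_down + d_s2sit)
    fsr[ramp_down] = _FSR_LOAD - (_FSR_LOAD - _FSR_SIT) * (t[ramp_down] - t_ramp_down) / d_s2sit

    pulse_n = int(round(_STEP_PULSE_S * rate))
    # single-humped stance-load bump (load peaks once at mid-stance)
    bump = np.sin(np.pi * np.arange(pulse_n) / pulse_n)
    for st in step_times:
        i0 = int(round(st * rate))
        i1 = min(i0 + pulse_n, n)
        fsr[i0:i1] += _FSR_STEP_BUMP * bump[: i1 - i0]

    # ---- stride lengths and per-stride pulse amplitudes
    sd_sl = g.stride_cv_nominal / 100.0 * g.stride_len_mean
    stride_lengths = np.clip(
        rng.normal(g.stride_len_mean, sd_sl, size=g.n_strides), 0.05, None
    )
    # stride i spans detected steps (2i, 2i+2); amplitude calibrated so the
    # mean rectified acceleration over the span inverts SL = 0.98*(mean|a|)^(1/3)
    unit = _pulse(pulse_n)
    accel_burst = np.zeros(n)
    amps = np.zeros(n_steps)
    for i in range(g.n_strides):
        a, b = step_times[2 * i], step_times[2 * i + 2]
        n_span = max(int(round((b - a) * rate)), 1)
        target_mean_abs = (stride_lengths[i] / 0.98) ** 3
        amp = target_mean_abs * n_span / (2.0 * np.sum(np.abs(unit)))
        amps[2 * i] = amps[2 * i + 1] = amp
    amps[-1] = amps[-2]  # trailing step reuses the last stride's amplitude
    for st, amp in zip(step_times, amps):
        i0 = int(round(st * rate))
        i1 = min(i0 + pulse_n, n)
        accel_burst[i0:i1] += amp * unit[: i1 - i0]

    noise_std = 0.3 * soil.grain_noise_level if soil is not None else 0.0
    accel_z = GRAVITY + accel_burst + noise_std * rng.standard_normal(n)
    accel_x = noise_std * rng.standard_normal(n)
    accel_y = noise_std * rng.standard_normal(n)

    meta = {"trial": "tug"}
    if soil is not None:
        meta["soil"] = soil.name
    rec = Recording(
        sample_rate=rate, t=t,
        accel_x=accel_x, accel_y=accel_y, accel_z=accel_z,
        fsr={"heel": fsr}, meta=meta,
    )

    peak_times = step_times + _STEP_PEAK_OFFSET_S
    phases = TUGPhases(
        t_start=t_ramp_up + d_s2s / 2.0,
        t_stand_end=float(peak_times[0]),
        t_turn_start=float(peak_times[g.n_strides]),
        t_turn_end=float(peak_times[g.n_strides + 1]),
        t_walkback_end=float(peak_times[-1]),
        t_end=t_ramp_down + d_s2sit / 2.0,
    )
    gt = TUGGroundTruth(
        phases=phases,
        step_times=peak_times,
        stride_lengths=stride_lengths,
        cadence_mean=g.cadence_mean,
        cadence_cv_nominal=g.cadence_cv_nominal,
        stride_cv_nominal=g.stride_cv_nominal,
        meta=dict(meta),
    )
    return rec, gt


def healthy_profile(seed: int = 0) -> GaitProfile:
    """A brisk, regular walker: short TUG time, low variability."""
    return GaitProfile(
        n_strides=6, cadence_mean=120.0, cadence_cv_nominal=2.0,
        stride_len_mean=1.0, stride_cv_nominal=2.0,
        phase_durations=(1.2, 1.2, 1.2), seed=seed,
    )


def impaired_profile(seed: int = 0) -> GaitProfile:
    """A slow, irregular walker: long TUG time, high variability."""
    return GaitProfile(
        n_strides=6, cadence_mean=85.0, cadence_cv_nominal=12.0,
        stride_len_mean=0.6, stride_cv_nominal=12.0,
        phase_durations=(2.5, 3.0, 2.5), seed=seed,
    )
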