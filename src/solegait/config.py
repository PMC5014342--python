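"""Configuration for the solegait pipelines.

A single nested mapping holds every tunable default of the analysis chain,
so experiments are declarative: load a YAML file, override keys, pass the
result to any pipeline.  Unknown keys are rejected to catch typos early.

Sections
--------
``strike``
    Heel-strike detection and preprocessing: FSR hysteresis fractions,
    Savitzky-Golay smoothing parameters, maximum window duration.
``soil``
    Spectral-centroid method, exclusion-region override, weight-optimisation
    controls.
``gait``
    Step detection (minimum inter-step interval, peak prominence, low-pass
    cut-off) and the single-instrumented-foot stride convention.
``risk``
    The proportionality constant ``alpha_c`` of the risk index
    ``Risk = alpha * (CV_cad + CV_SL)`` with ``alpha = alpha_c / speed``.
``cue``
    Vibrotactile pulse duration and the cadence uplift fraction.
``io``
    Whether input acceleration is in g (converted to m/s² on read).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: standard gravity, m/s² per g
G = 9.80665

DEFAULTS: dict[str, dict[str, Any]] = {
    "strike": {
        "onset_frac": 0.3,      # FSR rise threshold, fraction of channel max
        "release_frac": 0.1,    # FSR release threshold (hysteresis)
        "sg_order": 3,          # Savitzky-Golay polynomial order
        "sg_window": 11,        # Savitzky-Golay window length (odd samples)
        "max_window_ms": 250.0, # cap strike windows to the impact transient
    },
    "soil": {
        "centroid_method": "area",    # "area" (lamina) or "point" (unit masses)
        "exclusion_x_max": None,      # override fitted region; None = fit from data
        "exclusion_y_max": None,
        "exclusion_margin": 1.5,      # fitted region = data bounding box x margin
        "weight_sparsity": 0.05,      # zero weights below this fraction of the norm
        "n_restarts": 24,             # random restarts of the weight optimiser
    },
    "gait": {
        "min_interval_s": 0.3,   # minimum step separation
        "prominence_frac": 0.5,  # peak prominence as fraction of signal std
        "lowpass_hz": 10.0,      # low-pass cut-off for the accel magnitude
        "single_foot": False,    # True: double every other step interval for strides
        "fsr_tolerance": 0.2,    # accel/FSR step-count disagreement triggering fallback
        "load_sustain_s": 0.5,   # load must stay across threshold this long
    },
    "risk": {
        "alpha_c": 1.0,          # alpha = alpha_c / walking speed (dimensionless)
    },
    "cue": {
        "pulse_duration_s": 0.050,  # vibrotactile pulse width
        "uplift": 0.10,             # cue frequency = (1 + uplift) x baseline cadence
    },
    "io": {
        "accel_in_g": False,     # convert acceleration from g to m/s² on read
    },
    "seed": 0,
}


def default_config() -> dict:
    """Return a deep copy of the default configuration."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    for key, value in override.items():
        here = f"{path}{key}"
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"section {here!r} must be a mapping")
            _merge(base[key], value, here + ".")
        else:
            base[key] = value
    return base


def make_config(overrides: Mapping | None = None) -> dict:
    """Defaults merged with ``overrides``; unknown keys raise :class:`ConfigError`."""
    cfg = default_config()
    if overrides:
        _merge(cfg, overrides)
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file on top of the defaults.

    ``None`` returns the plain defaults.
    """
    if path is None:
        return default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return make_config(data)
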