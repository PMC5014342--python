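"""End-to-end analysis pipelines tying the modules together.

Two entry points mirror the two study regimes:

* :func:`run_soil_pipeline` — fit a terrain classifier from labelled
  heel-strike recordings and report its detection rate;
* :func:`run_tug_pipeline` — score one TUG trial against baseline
  (reference-terrain) trials: phases, gait parameters, risk index, mobility
  category, and the cue decision with its pulse schedule.

Both take the nested configuration mapping from :mod:`solegait.config` and
return plain-dict JSON-ready reports, so the CLI and library callers share
one code path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import cueing, soil, tug
from .config import make_config
from .errors import FormatError
from .heelstrike import detect_strikes, preprocess_strike
from .sensor_io import Recording, read_recording


def _strike_features(
    rec: Recording, cfg: dict
) -> list[tuple[soil.FeatureVector, str | None]]:
    """Detect, preprocess and featurize every strike in one recording."""
    sc = cfg["strike"]
    out = []
    for w in detect_strikes(
        rec,
        onset_frac=sc["onset_frac"],
        release_frac=sc["release_frac"],
        max_window_ms=sc["max_window_ms"],
    ):
        pw = preprocess_strike(w, sg_order=sc["sg_order"], sg_window=sc["sg_window"])
        spectrum = soil.compute_spectrum(pw, rec.sample_rate)
        fv = soil.extract_features(
            pw, spectrum, centroid_method=cfg["soil"]["centroid_method"]
        )
        out.append((fv, w.soil_label))
    return out


def labelled_features(
    recordings: list[Recording], cfg: dict | None = None
) -> list[tuple[soil.FeatureVector, str]]:
    """Strike feature vectors with their soil labels, over many recordings."""
    cfg = cfg or make_config()
    labeled = []
    for rec in recordings:
        for fv, label in _strike_features(rec, cfg):
            if label is None:
                raise FormatError("recording lacks a 'soil' label in meta")
            labeled.append((fv, label))
    return labeled


def _load_dir(path: str | Path) -> list[Recording]:
    files = sorted(
        p for p in Path(path).iterdir() if p.suffix in {".csv", ".jsonl", ".ndjson"}
    )
    if not files:
        raise FormatError(f"no recordings found in {path}")
    return [read_recording(p) for p in files]


def run_soil_pipeline(
    train: list[Recording] | str | Path,
    test: list[Recording] | str | Path | None = None,
    config: dict | None = None,
    seed: int = 0,
    model_out: str | Path | None = None,
) -> dict:
    """Fit the weighted-feature soil model and evaluate detection rates.

    ``train``/``test`` are recording lists or directories of recording
    files; held-in evaluation is used when ``test`` is omitted.  The report
    carries the detection rate of the full model and of the centroid-only
    baseline on the same data.
    """
    cfg = config or make_config()
    if not isinstance(train, list):
        train = _load_dir(train)
    train_feats = labelled_features(train, cfg)
    sl = cfg["soil"]
    fit_kwargs = dict(
        seed=seed,
        n_restarts=sl["n_restarts"],
        weight_sparsity=sl["weight_sparsity"],
        exclusion_margin=sl["exclusion_margin"],
        exclusion_override=(sl["exclusion_x_max"], sl["exclusion_y_max"]),
    )
    model = soil.fit_soil_model(train_feats, **fit_kwargs)
    baseline = soil.centroid_only_model(train_feats, **fit_kwargs)

    if test is None:
        test_feats = train_feats
    else:
        if not isinstance(test, list):
            test = _load_dir(test)
        test_feats = labelled_features(test, cfg)

    if model_out is not None:
        model.save(model_out)
    report = {
        "n_train_strikes": len(train_feats),
        "n_test_strikes": len(test_feats),
        "classes": model.classes,
        "weights": {
            name: float(w) for name, w in zip(soil.FEATURE_NAMES, model.weights)
        },
        "separable": bool(model.separable),
        "detection_rate": soil.detection_rate(model, test_feats),
        "centroid_only_detection_rate": soil.detection_rate(baseline, test_feats),
        "seed": seed,
    }
    return report


def score_tug(rec: Recording, config: dict | None = None) -> dict:
    """Segment and score one TUG trial; returns the per-trial report block."""
    cfg = config or make_config()
    gc = cfg["gait"]
    phases = tug.segment_tug(
        rec,
        sustain_s=gc["load_sustain_s"],
        step_kwargs=dict(
            min_interval_s=gc["min_interval_s"],
            prominence_frac=gc["prominence_frac"],
            lowpass_hz=gc["lowpass_hz"],
        ),
    )
    steps = tug.detect_steps(
        rec,
        phases,
        min_interval_s=gc["min_interval_s"],
        prominence_frac=gc["prominence_frac"],
        lowpass_hz=gc["lowpass_hz"],
        fsr_tolerance=gc["fsr_tolerance"],
    )
    gp = tug.gait_params(steps, rec, phases, single_foot=gc["single_foot"])
    risk = tug.risk_of_falling(gp, alpha_c=cfg["risk"]["alpha_c"])
    return {
        "phases": {
            "t_start": phases.t_start,
            "t_stand_end": phases.t_stand_end,
            "t_turn_start": phases.t_turn_start,
            "t_turn_end": phases.t_turn_end,
            "t_walkback_end": phases.t_walkback_end,
            "t_end": phases.t_end,
            "tug_time_s": phases.tug_time,
        },
        "category": tug.categorize_tug(phases),
        "steps": {"count": len(steps), "source": steps.source},
        "gait": {
            "cadence_mean_spm": gp.cadence_mean,
            "stride_length_mean_m": float(np.mean(gp.stride_lengths)),
            "speed_m_s": gp.speed,
        },
        "risk": {
            "cv_cadence_pct": risk.cv_cadence,
            "cv_stride_pct": risk.cv_stride,
            "alpha": risk.alpha,
            "risk_pct": risk.risk,
        },
        "_gait_params": gp,  # stripped before JSON serialization
    }


def run_tug_pipeline(
    recording: Recording | str | Path,
    baseline_recordings: list[Recording] | list[str | Path],
    config: dict | None = None,
) -> dict:
    """Score a TUG trial against baseline trials and decide on cueing.

    The baseline trials (reference terrain, typically concrete) set both the
    preferred cadence — hence the cue frequency at +10% — and the reference
    risk the current trial is compared against.
    """
    cfg = config or make_config()
    if not isinstance(recording, Recording):
        recording = read_recording(recording)
    baselines = [
        r if isinstance(r, Recording) else read_recording(r)
        for r in baseline_recordings
    ]
    trial = score_tug(recording, cfg)
    baseline_reports = [score_tug(r, cfg) for r in baselines]

    base_cadence = cueing.baseline_cadence(
        [r["_gait_params"] for r in baseline_reports]
    )
    reference_risk = float(
        np.mean([r["risk"]["risk_pct"] for r in baseline_reports])
    )
    freq = cueing.cue_frequency(base_cadence, uplift=cfg["cue"]["uplift"])
    cue_on = cueing.should_cue(trial["risk"]["risk_pct"], reference_risk)
    schedule = cueing.generate_schedule(
        freq,
        duration=trial["phases"]["tug_time_s"],
        pulse_duration=cfg["cue"]["pulse_duration_s"],
    )

    def strip(d: dict) -> dict:
        return {k: v for k, v in d.items() if not k.startswith("_")}

    return {
        "trial": strip(trial),
        "baseline": {
            "n_trials": len(baseline_reports),
            "cadence_spm": base_cadence,
            "reference_risk_pct": reference_risk,
        },
        "cue": {
            "active": bool(cue_on),
            "frequency_ppm": freq,
            "pulse_duration_s": schedule.pulse_duration,
            "n_pulses": int(len(schedule.pulse_times)),
        },
    }


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a pipeline report as stable, human-readable JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
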