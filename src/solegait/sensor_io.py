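"""Reading, writing, validating and resampling multichannel insole recordings.

A :class:`Recording` is a uniformly sampled multichannel stream from an
instrumented insole: tri-axial acceleration (m/s²), one or more
force-sensitive-resistor (FSR) channels in arbitrary non-negative sensor
units, and an optional bend channel.  Two self-describing single-file
dialects are supported:

* **CSV** — ``# key=value`` comment header lines carrying ``sample_rate``
  and metadata, then columns ``t, accel_x, accel_y, accel_z,
  fsr_<name>..., bend``.
* **JSON-Lines** — a first header object ``{"sample_rate": ..., "meta":
  {...}}`` followed by one sample object per line.

Timestamps are regenerated from ``sample_rate`` when absent, matching the
fixed-rate streaming of the hardware the formats describe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import G
from .errors import FormatError, ParameterError, TimingError

_REL_TOL = 1e-6  # relative tolerance on timestamp spacing


@dataclass
class Recording:
    """A uniformly sampled multichannel insole sensor stream.

    Parameters
    ----------
    sample_rate : float
        Sampling rate in Hz (positive).
    t : ndarray
        Seconds per sample, strictly increasing, spacing 1/sample_rate.
    accel_x, accel_y, accel_z : ndarray
        Acceleration in m/s².
    fsr : dict[str, ndarray]
        One or more non-negative force-channel series, keyed by sensor name
        (e.g. ``"heel"``).
    bend : ndarray, optional
        Dimensionless bend-sensor series.
    meta : dict
        Free-form key/value metadata (subject id, soil label, trial id).
    """

    sample_rate: float
    t: np.ndarray
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    fsr: dict[str, np.ndarray]
    bend: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size == 0:
            self.t = np.arange(len(self.accel_z)) / self.sample_rate
        for name in ("accel_x", "accel_y", "accel_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.fsr = {k: np.asarray(v, dtype=float) for k, v in self.fsr.items()}
        if self.bend is not None:
            self.bend = np.asarray(self.bend, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise FormatError("recording must have at least 2 samples")
        if not self.fsr:
            raise FormatError("recording needs at least one FSR channel")
        for name, arr in self.channels().items():
            if len(arr) != n:
                raise FormatError(
                    f"channel {name!r} has length {len(arr)}, expected {n}"
                )
        for name, arr in self.fsr.items():
            if np.any(arr < 0):
                raise FormatError(f"FSR channel {name!r} has negative values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise TimingError("timestamps must be strictly increasing")
        expected = 1.0 / self.sample_rate
        if np.any(np.abs(dt - expected) > _REL_TOL * expected):
            raise TimingError(
                "timestamp spacing deviates from 1/sample_rate beyond tolerance"
            )

    # -- convenience --------------------------------------------------------

    def channels(self) -> dict[str, np.ndarray]:
        """All named data channels (excluding ``t``)."""
        out = {
            "accel_x": self.accel_x,
            "accel_y": self.accel_y,
            "accel_z": self.accel_z,
        }
        out.update({f"fsr_{k}": v for k, v in self.fsr.items()})
        if self.bend is not None:
            out["bend"] = self.bend
        return out

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    def heel_fsr(self) -> np.ndarray:
        """The heel FSR channel: ``fsr['heel']`` if present, else the first one."""
        if "heel" in self.fsr:
            return self.fsr["heel"]
        return next(iter(self.fsr.values()))

    def total_fsr(self) -> np.ndarray:
        """Sum of all FSR channels (total plantar load proxy)."""
        return np.sum(list(self.fsr.values()), axis=0)

    def accel_magnitude(self) -> np.ndarray:
        """Euclidean norm of the three acceleration axes."""
        return np.sqrt(self.accel_x**2 + self.accel_y**2 + self.accel_z**2)


# -- construction helpers ---------------------------------------------------

_MANDATORY = ("accel_z",)
_ACCEL_COLS = ("accel_x", "accel_y", "accel_z")


def _from_columns(
    columns: dict[str, np.ndarray],
    sample_rate: float,
    meta: dict,
    accel_in_g: bool = False,
) -> Recording:
    for col in _MANDATORY:
        if col not in columns:
            raise FormatError(f"mandatory channel {col!r} missing")
    fsr = {
        k[len("fsr_"):]: np.asarray(v, float)
        for k, v in columns.items()
        if k.startswith("fsr_")
    }
    if not fsr:
        raise FormatError("at least one fsr_<name> channel is required")
    n = len(columns["accel_z"])
    zeros = np.zeros(n)
    scale = G if accel_in_g else 1.0

    known = set(_ACCEL_COLS) | {"t", "bend"} | {f"fsr_{k}" for k in fsr}
    extra = {k: list(np.asarray(v)) for k, v in columns.items() if k not in known}
    if extra:
        meta = {**meta, "extra_columns": extra}

    t = np.asarray(columns["t"], float) if "t" in columns else np.arange(n) / sample_rate
    return Recording(
        sample_rate=sample_rate,
        t=t,
        accel_x=np.asarray(columns.get("accel_x", zeros), float) * scale,
        accel_y=np.asarray(columns.get("accel_y", zeros), float) * scale,
        accel_z=np.asarray(columns["accel_z"], float) * scale,
        fsr=fsr,
        bend=np.asarray(columns["bend"], float) if "bend" in columns else None,
        meta=meta,
    )


# -- CSV dialect ------------------------------------------------------------

def _read_csv(path: Path, rate_override: float | None, accel_in_g: bool) -> Recording:
    meta: dict = {}
    sample_rate = rate_override
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key == "sample_rate":
                    if rate_override is None:
                        sample_rate = float(value)
                else:
                    meta[key] = value
    if sample_rate is None:
        raise FormatError(f"{path}: no '# sample_rate=' header and no rate override")
    df = pd.read_csv(path, skiprows=header_lines)
    return _from_columns(
        {c: df[c].to_numpy() for c in df.columns}, sample_rate, meta, accel_in_g
    )


def _write_csv(rec: Recording, path: Path) -> None:
    cols = {"t": rec.t, **rec.channels()}
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={rec.sample_rate!r}\n")
        for key, value in rec.meta.items():
            if key == "extra_columns":
                continue
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


# -- JSON-Lines dialect -----------------------------------------------------

def _read_jsonl(path: Path, rate_override: float | None, accel_in_g: bool) -> Recording:
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        header = json.loads(first)
        if "sample_rate" not in header:
            raise FormatError(f"{path}: first JSONL object must declare sample_rate")
        sample_rate = rate_override or float(header["sample_rate"])
        meta = dict(header.get("meta", {}))
        rows = [json.loads(line) for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path}: no samples")
    columns = {key: np.array([row[key] for row in rows]) for key in rows[0]}
    return _from_columns(columns, sample_rate, meta, accel_in_g)


def _write_jsonl(rec: Recording, path: Path) -> None:
    channels = {"t": rec.t, **rec.channels()}
    meta = {k: v for k, v in rec.meta.items() if k != "extra_columns"}
    with open(path, "w") as fh:
        fh.write(json.dumps({"sample_rate": rec.sample_rate, "meta": meta}) + "\n")
        for i in range(len(rec)):
            fh.write(json.dumps({k: v[i] for k, v in channels.items()}) + "\n")


# -- public API -------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"


def read_recording(
    path: str | Path,
    format: str | None = None,
    rate: float | None = None,
    accel_in_g: bool = False,
) -> Recording:
    """Read a recording from ``path``.

    Parameters
    ----------
    format : {"csv", "jsonl"}, optional
        Inferred from the suffix when omitted.
    rate : float, optional
        Overrides the sample rate declared in the file.
    accel_in_g : bool
        Interpret stored acceleration as g and convert to m/s².
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, rate, accel_in_g)
    if fmt == "jsonl":
        return _read_jsonl(path, rate, accel_in_g)
    raise ParameterError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write ``rec`` so that :func:`read_recording` reproduces it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "jsonl":
        _write_jsonl(rec, path)
    else:
        raise ParameterError(f"unknown format {fmt!r}")


def resample(rec: Recording, target_rate: float) -> Recording:
    """Linear-interpolation resampling onto a uniform grid at ``target_rate``.

    The duration is preserved to within one sample period; a no-op when the
    target equals the current rate.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    if np.isclose(target_rate, rec.sample_rate):
        return rec
    t_new = np.arange(rec.t[0], rec.t[-1] + 0.5 / target_rate, 1.0 / target_rate)
    t_new = t_new[t_new <= rec.t[-1] + 1e-12]

    def interp(arr: np.ndarray) -> np.ndarray:
        return np.interp(t_new, rec.t, arr)

    return Recording(
        sample_rate=target_rate,
        t=t_new,
        accel_x=interp(rec.accel_x),
        accel_y=interp(rec.accel_y),
        accel_z=interp(rec.accel_z),
        fsr={k: interp(v) for k, v in rec.fsr.items()},
        bend=interp(rec.bend) if rec.bend is not None else None,
        meta=dict(rec.meta),
    )
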