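"""Terrain (soil-type) differentiation from heel-strike vibration spectra.

Each preprocessed heel-strike window is converted to a one-sided mean
absolute FFT magnitude spectrum.  Two summaries feed a per-strike feature
vector:

* the **spectral centroid** ``(Sx, Sy)`` — the centroid of the region under
  the magnitude curve.  With the lamina (area) interpretation,

  .. math::  S_x = \\frac{\\sum_i f_i m_i}{\\sum_i m_i}, \\qquad
             S_y = \\frac{\\sum_i m_i^2 / 2}{\\sum_i m_i},

  i.e. the centre of mass of the area between the curve and the frequency
  axis.  A literal unit-point-mass variant (each bin a unit mass at
  ``(f_i, m_i)``) is kept as an option.

* four **time-domain statistics** of the preprocessed window: mean,
  standard deviation, variance and kurtosis (standardized fourth central
  moment; a Gaussian scores 3).

The six features are standardized and combined into a single
**differentiation level** ``L = sum_i W_i F_i``; the weights ``W_i`` are
optimized to spread the per-class L distributions apart, and class
boundaries are thresholds at the midpoints between adjacent class means on
the L axis.  An exclusion rectangle in centroid space flags outlier strikes
(deformable terrain produces erratic impulse responses that scatter off
their cluster).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.stats import kurtosis as _scipy_kurtosis

from .errors import (
    FitError,
    ModelStateError,
    ParameterError,
    UndefinedResultError,
)
from .heelstrike import ProcessedWindow

FEATURE_NAMES = ("Sx", "Sy", "mean", "std", "variance", "kurtosis")

#: printed exclusion-region bounds used when a model is built without data
DEFAULT_EXCLUSION = (50.0, 8e-4)


@dataclass
class Spectrum:
    """One-sided mean absolute FFT magnitude spectrum."""

    freqs: np.ndarray  # Hz per bin, ascending from 0 to Nyquist
    mags: np.ndarray   # mean absolute magnitude per bin, >= 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mags = np.asarray(self.mags, dtype=float)
        if len(self.freqs) != len(self.mags):
            raise ParameterError("freqs and mags must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("freqs must be ascending")
        if np.any(self.mags < 0):
            raise ParameterError("mags must be non-negative")


@dataclass
class Centroid:
    """Spectral centroid coordinates: Sx in Hz, Sy in magnitude units."""

    Sx: float
    Sy: float


@dataclass
class FeatureVector:
    """Per-strike features: centroid coordinates + time-domain statistics."""

    Sx: float
    Sy: float
    mean: float
    std: float
    variance: float
    kurtosis: float
    kurtosis_degenerate: bool = False  # zero-variance window, kurtosis forced to 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class SoilModel:
    """Fitted weighted-feature soil classifier.

    ``classes`` are ordered by ascending class-mean level L; ``thresholds``
    are the ``len(classes) - 1`` midpoints between adjacent class means.
    ``exclusion_region`` is ``(x_max, y_max)``: a strike whose centroid
    falls outside ``[0, x_max] x [0, y_max]`` is an outlier.
    """

    classes: list[str]
    weights: np.ndarray
    feature_loc: np.ndarray     # per-feature location (training mean)
    feature_scale: np.ndarray   # per-feature scale (training std)
    class_L_mean: dict[str, float]
    class_L_std: dict[str, float]
    thresholds: np.ndarray
    exclusion_region: tuple[float, float] = DEFAULT_EXCLUSION
    seed: int = 0
    separable: bool = True
    objective: float = 0.0
    fitted: bool = field(default=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_loc = np.asarray(self.feature_loc, dtype=float)
        self.feature_scale = np.asarray(self.feature_scale, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.thresholds) != len(self.classes) - 1:
            raise ParameterError("need len(classes) - 1 thresholds")
        # a degenerate (non-separable) fit may place thresholds on top of
        # each other; a usable model must keep them strictly increasing
        if self.separable and np.any(np.diff(self.thresholds) <= 0):
            raise ParameterError("thresholds must be strictly increasing")
        if not np.all(np.isfinite(self.weights)):
            raise ParameterError("weights must be finite")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("weights", "feature_loc", "feature_scale", "thresholds"):
            d[key] = [float(v) for v in d[key]]
        d["exclusion_region"] = [float(v) for v in self.exclusion_region]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SoilModel":
        d = dict(d)
        d["exclusion_region"] = tuple(d["exclusion_region"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SoilModel":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


# -- spectra and features ----------------------------------------------------

def compute_spectrum(w: ProcessedWindow, sample_rate: float) -> Spectrum:
    """One-sided mean absolute magnitude spectrum of a preprocessed window.

    Magnitudes are |FFT| divided by the padded length ("mean absolute
    value" normalisation), over ``padded_length/2 + 1`` bins from 0 Hz to
    Nyquist.
    """
    n = w.padded_length
    mags = np.abs(np.fft.rfft(w.signal)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return Spectrum(freqs=freqs, mags=mags)


def spectral_centroid(s: Spectrum, method: str = "area") -> Centroid:
    """Centroid of the magnitude spectrum.

    ``method="area"`` (default) treats the region under the magnitude curve
    as a lamina: Sx = sum(f*m)/sum(m), Sy = sum(m^2/2)/sum(m).
    ``method="point"`` places a unit mass at each bin above a floor of
    1e-12 x max(mags): Sx = mean frequency, Sy = mean magnitude of those
    bins.
    """
    total = float(np.sum(s.mags))
    if total <= 0:
        raise UndefinedResultError("centroid undefined for an all-zero spectrum")
    if method == "area":
        sx = float(np.sum(s.freqs * s.mags) / total)
        sy = float(np.sum(s.mags**2 / 2.0) / total)
    elif method == "point":
        floor = 1e-12 * float(np.max(s.mags))
        mask = s.mags > floor
        sx = float(np.mean(s.freqs[mask]))
        sy = float(np.mean(s.mags[mask]))
    else:
        raise ParameterError(f"unknown centroid method {method!r}")
    return Centroid(Sx=sx, Sy=sy)


def extract_features(
    w: ProcessedWindow, s: Spectrum, centroid_method: str = "area"
) -> FeatureVector:
    """Per-strike feature vector: centroid coords + time-domain moments.

    Kurtosis is the standardized fourth central moment (Gaussian -> 3); a
    zero-variance window gets kurtosis 0 with the degenerate flag set.
    """
    c = spectral_centroid(s, method=centroid_method)
    x = w.signal
    mean = float(np.mean(x))
    var = float(np.var(x))  # population variance, consistent with the moments
    std = float(np.sqrt(var))
    if var <= 0:
        kurt, degenerate = 0.0, True
    else:
        kurt = float(_scipy_kurtosis(x, fisher=False, bias=True))
        degenerate = False
    return FeatureVector(
        Sx=c.Sx, Sy=c.Sy, mean=mean, std=std, variance=var,
        kurtosis=kurt, kurtosis_degenerate=degenerate,
    )


# -- level L and model fitting ------------------------------------------------

def _scale_features(X: np.ndarray, loc: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - loc) / scale


def differentiation_level(f: FeatureVector, model: SoilModel) -> float:
    """Weighted sum of standardized features: L = sum_i W_i * scaled(F_i)."""
    if not model.fitted:
        raise ModelStateError("model has no fitted feature scaling")
    z = _scale_features(f.as_array(), model.feature_loc, model.feature_scale)
    return float(np.dot(model.weights, z))


def _separation_objective(
    w: np.ndarray, Z: np.ndarray, groups: list[np.ndarray], eps: float = 1e-6
) -> float:
    """Min over class pairs of |mean_L difference| / (sum of L stds + eps)."""
    norm = np.linalg.norm(w)
    if norm == 0:
        return 0.0
    L = Z @ (w / norm)
    stats = [(float(np.mean(L[g])), float(np.std(L[g]))) for g in groups]
    return min(
        abs(m1 - m2) / (s1 + s2 + eps)
        for (m1, s1), (m2, s2) in combinations(stats, 2)
    )


def _fisher_direction(Z: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Leading multiclass Fisher (LDA) direction; a strong optimiser start."""
    k = Z.shape[1]
    mu = Z.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for g in groups:
        mc = Z[g].mean(axis=0)
        d = Z[g] - mc
        Sw += d.T @ d
        Sb += len(g) * np.outer(mc - mu, mc - mu)
    try:
        vals, vecs = np.linalg.eig(np.linalg.pinv(Sw + 1e-9 * np.eye(k)) @ Sb)
    except np.linalg.LinAlgError:
        return np.zeros(k)
    return np.real(vecs[:, np.argmax(np.real(vals))])


def fit_soil_model(
    labeled: list[tuple[FeatureVector, str]],
    seed: int = 0,
    n_restarts: int = 24,
    weight_sparsity: float = 0.05,
    exclusion_margin: float = 1.5,
    exclusion_override: tuple[float | None, float | None] = (None, None),
    feature_mask: np.ndarray | None = None,
) -> SoilModel:
    """Fit weights, class thresholds and the exclusion region from labelled strikes.

    Features are standardized to zero mean / unit variance over the training
    set.  Unit-norm weights are chosen to maximize the minimum pairwise
    Fisher-like separation of the per-class level distributions,

    ``min_{c1 != c2} |mean_L(c1) - mean_L(c2)| / (std_L(c1) + std_L(c2) + eps)``,

    by seeded random-restart Nelder-Mead (deterministic given the seed).
    Weights below ``weight_sparsity`` x the norm are zeroed afterwards
    (cheap subset selection).  Classes are then ordered by mean L and the
    thresholds placed at midpoints of adjacent class means.  The exclusion
    rectangle is the training centroids' bounding box (anchored at the
    origin) scaled by ``exclusion_margin``, unless overridden.
    """
    if not labeled:
        raise FitError("empty training set")
    labels = [lab for _, lab in labeled]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise FitError("need at least 2 classes")
    for c in classes:
        if labels.count(c) < 3:
            raise FitError(f"class {c!r} has fewer than 3 strikes")

    X = np.array([f.as_array() for f, _ in labeled])
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant feature carries no information
    Z = _scale_features(X, loc, scale)
    groups = [np.array([i for i, lab in enumerate(labels) if lab == c]) for c in classes]

    rng = np.random.default_rng(seed)
    k = X.shape[1]
    if feature_mask is None:
        mask = np.ones(k, dtype=bool)
    else:
        mask = np.asarray(feature_mask, dtype=bool)
        if mask.shape != (k,) or not mask.any():
            raise FitError("feature_mask must select at least one feature")

    def neg_obj(w: np.ndarray) -> float:
        return -_separation_objective(w * mask, Z, groups)

    # candidate directions: coordinate axes, the Fisher discriminant, and the
    # best of a large screened pool of random directions; each is then
    # polished with Nelder-Mead
    starts = [np.eye(k)[i] for i in range(k) if mask[i]]
    lda = _fisher_direction(Z, groups) * mask
    if np.linalg.norm(lda) > 0:
        starts.append(lda / np.linalg.norm(lda))
    pool = rng.standard_normal((200 * max(n_restarts, 1), k)) * mask
    scores = np.array([-neg_obj(w) for w in pool])
    starts += list(pool[np.argsort(scores)[::-1][:n_restarts]])

    best_w, best_obj = starts[0], -np.inf
    for w0 in starts:
        res = minimize(
            neg_obj,
            w0,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if -res.fun > best_obj:
            best_obj, best_w = -res.fun, res.x * mask

    w = best_w / np.linalg.norm(best_w)
    # sparsify small contributions, but only when that costs little
    # separation: a tiny weight on a widely spread feature can be decisive
    w_sparse = np.where(np.abs(w) < weight_sparsity, 0.0, w)
    if np.linalg.norm(w_sparse) > 0:
        w_sparse = w_sparse / np.linalg.norm(w_sparse)
        if _separation_objective(w_sparse, Z, groups) >= 0.9 * best_obj:
            w = w_sparse
    # deterministic sign convention: dominant component positive
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    best_obj = _separation_objective(w, Z, groups)

    L = Z @ w
    class_mean = {c: float(np.mean(L[g])) for c, g in zip(classes, groups)}
    class_std = {c: float(np.std(L[g], ddof=1)) for c, g in zip(classes, groups)}
    order = sorted(classes, key=lambda c: class_mean[c])
    means = np.array([class_mean[c] for c in order])
    thresholds = (means[:-1] + means[1:]) / 2.0

    separable = best_obj > 1e-6
    x_max = exclusion_override[0]
    y_max = exclusion_override[1]
    if x_max is None:
        x_max = exclusion_margin * float(np.max(X[:, 0]))
    if y_max is None:
        y_max = exclusion_margin * float(np.max(X[:, 1]))

    return SoilModel(
        classes=order,
        weights=w,
        feature_loc=loc,
        feature_scale=scale,
        class_L_mean=class_mean,
        class_L_std=class_std,
        thresholds=thresholds,
        exclusion_region=(float(x_max), float(y_max)),
        seed=seed,
        separable=separable,
        objective=float(best_obj),
        fitted=True,
    )


def classify(f: FeatureVector, model: SoilModel) -> tuple[str, bool]:
    """Assign the class whose L interval contains L(f); flag centroid outliers.

    A strike is an outlier when its centroid falls outside the exclusion
    rectangle ``[0, x_max] x [0, y_max]``; the class is still reported.
    Ties exactly at a threshold go to the lower-L class.
    """
    if not model.fitted:
        raise ModelStateError("model is not fitted")
    x_max, y_max = model.exclusion_region
    outlier = not (0.0 <= f.Sx <= x_max and 0.0 <= f.Sy <= y_max)
    level = differentiation_level(f, model)
    idx = int(np.searchsorted(model.thresholds, level, side="left"))
    return model.classes[idx], outlier


def detection_rate(
    model: SoilModel, labeled: list[tuple[FeatureVector, str]]
) -> float:
    """Fraction of strikes classified correctly and not flagged as outliers."""
    if not labeled:
        raise UndefinedResultError("detection rate undefined for an empty list")
    hits = 0
    for f, lab in labeled:
        pred, outlier = classify(f, model)
        if pred == lab and not outlier:
            hits += 1
    return hits / len(labeled)


def centroid_only_model(
    labeled: list[tuple[FeatureVector, str]], seed: int = 0, **kwargs
) -> SoilModel:
    """Fit a classifier restricted to the centroid coordinates (Sx, Sy).

    The weight optimisation is constrained to the (Sx, Sy) subspace,
    mimicking classification by centroid position alone.  Serves as the
    baseline the full weighted-feature level improves on.
    """
    mask = np.array([name in ("Sx", "Sy") for name in FEATURE_NAMES])
    return fit_soil_model(labeled, seed=seed, feature_mask=mask, **kwargs)
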