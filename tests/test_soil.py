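import numpy as np
import pytest

import solegait as sg
from solegait.errors import FitError, ModelStateError, UndefinedResultError
from solegait.soil import FEATURE_NAMES, Spectrum, _separation_objective


def _pw(signal):
    signal = np.asarray(signal, float)
    return sg.ProcessedWindow(
        signal=signal,
        padded_length=len(signal),
        window_applied=False,
        filter_params=(0, 0),
    )


def _fv(**kw):
    base = dict(Sx=0.0, Sy=0.0, mean=0.0, std=0.0, variance=0.0, kurtosis=0.0)
    base.update(kw)
    return sg.FeatureVector(**base)


class TestSpectrum:
    def test_zero_signal_zero_mags(self):
        s = sg.compute_spectrum(_pw(np.zeros(128)), 1000.0)
        np.testing.assert_array_equal(s.mags, 0.0)
        assert len(s.mags) == 65

    def test_unit_impulse_flat_spectrum(self):
        x = np.zeros(128)
        x[0] = 1.0
        s = sg.compute_spectrum(_pw(x), 1000.0)
        np.testing.assert_allclose(s.mags, 1.0 / 128, atol=1e-15)

    def test_bin_aligned_sine_single_dominant_bin(self):
        # ~50 Hz sine placed exactly on bin 51 of a 1024-point, 1 kHz grid
        rate, n = 1000.0, 1024
        f = 51 * rate / n
        t = np.arange(n) / rate
        s = sg.compute_spectrum(_pw(np.sin(2 * np.pi * f * t)), rate)
        k = int(np.argmax(s.mags))
        assert s.freqs[k] == pytest.approx(f)
        assert abs(s.freqs[k] - 50.0) < rate / n  # within one bin of 50 Hz
        others = np.delete(s.mags, k)
        assert np.max(others) < 1e-10 * s.mags[k] + 1e-12
        # closed-form DFT magnitude of a bin-aligned unit sine: n/2 / n
        assert s.mags[k] == pytest.approx(0.5)


class TestCentroid:
    def test_single_bin_area_and_point(self):
        s = Spectrum(freqs=np.array([0.0, 10.0, 20.0]),
                     mags=np.array([0.0, 4.0, 0.0]))
        area = sg.spectral_centroid(s, "area")
        assert (area.Sx, area.Sy) == (10.0, 2.0)
        point = sg.spectral_centroid(s, "point")
        assert (point.Sx, point.Sy) == (10.0, 4.0)

    def test_two_equal_bins_symmetric(self):
        s = Spectrum(freqs=np.array([0.0, 10.0, 30.0]),
                     mags=np.array([0.0, 2.0, 2.0]))
        for method in ("area", "point"):
            c = sg.spectral_centroid(s, method)
            assert c.Sx == pytest.approx(20.0)

    def test_triangular_profile_centroid_at_peak(self):
        freqs = np.linspace(0.0, 100.0, 101)
        mags = np.where(freqs <= 50, freqs, 100 - freqs)
        c = sg.spectral_centroid(Spectrum(freqs=freqs, mags=mags), "area")
        assert c.Sx == pytest.approx(50.0)

    def test_area_method_matches_brute_force_lamina(self):
        rng = np.random.default_rng(3)
        freqs = np.linspace(0.0, 500.0, 257)
        mags = rng.random(257)
        c = sg.spectral_centroid(Spectrum(freqs=freqs, mags=mags), "area")
        # independent double-loop lamina summation
        num_x = num_y = den = 0.0
        for f, m in zip(freqs, mags):
            num_x += f * m
            num_y += m * m / 2.0
            den += m
        assert abs(c.Sx - num_x / den) <= 1e-9 * abs(num_x / den)
        assert abs(c.Sy - num_y / den) <= 1e-9 * abs(num_y / den)

    def test_zero_spectrum_undefined(self):
        s = Spectrum(freqs=np.array([0.0, 1.0]), mags=np.zeros(2))
        with pytest.raises(UndefinedResultError):
            sg.spectral_centroid(s)


class TestFeatures:
    def test_zero_window_degenerate_kurtosis(self):
        s = Spectrum(freqs=np.array([0.0, 1.0]), mags=np.array([0.0, 1.0]))
        f = sg.extract_features(_pw(np.zeros(8)), s)
        assert f.mean == f.std == f.variance == f.kurtosis == 0.0
        assert f.kurtosis_degenerate

    def test_square_alternation_moments(self):
        x = np.tile([1.0, -1.0], 8)
        s = Spectrum(freqs=np.array([0.0, 1.0]), mags=np.array([0.0, 1.0]))
        f = sg.extract_features(_pw(x), s)
        assert f.mean == 0.0
        assert f.variance == pytest.approx(1.0)
        assert f.kurtosis == pytest.approx(1.0)  # two-point distribution

    def test_moment_homogeneity_under_scaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=64)
        s = Spectrum(freqs=np.array([0.0, 1.0]), mags=np.array([0.0, 1.0]))
        f1 = sg.extract_features(_pw(x), s)
        f2 = sg.extract_features(_pw(3.0 * x), s)
        assert f2.mean == pytest.approx(3 * f1.mean)
        assert f2.std == pytest.approx(3 * f1.std)
        assert f2.variance == pytest.approx(9 * f1.variance)
        assert f2.kurtosis == pytest.approx(f1.kurtosis)

    def test_variance_equals_std_squared(self):
        rng = np.random.default_rng(5)
        s = Spectrum(freqs=np.array([0.0, 1.0]), mags=np.array([0.0, 1.0]))
        f = sg.extract_features(_pw(rng.normal(size=32)), s)
        assert f.variance == pytest.approx(f.std**2, rel=1e-12)


def _two_class_training(n=10, gap=10.0, jitter=0.05, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label, sx in (("a", 5.0), ("b", 5.0 + gap)):
        for _ in range(n):
            out.append((
                _fv(Sx=sx + jitter * rng.standard_normal(),
                    Sy=1.0 + jitter * rng.standard_normal(),
                    mean=0.5 + jitter * rng.standard_normal(),
                    std=1.0 + jitter * rng.standard_normal(),
                    variance=1.0 + jitter * rng.standard_normal(),
                    kurtosis=3.0 + jitter * rng.standard_normal()),
                label,
            ))
    return out


class TestLevelAndFit:
    def test_zero_weights_give_zero_level(self, soil_model):
        import dataclasses

        model = dataclasses.replace(soil_model, weights=np.zeros(6))
        assert sg.differentiation_level(_fv(Sx=123.0, std=9.0), model) == 0.0

    def test_one_hot_weight_selects_scaled_feature(self):
        model = _manual_model(weights=[1, 0, 0, 0, 0, 0],
                              loc=[10.0] * 6, scale=[2.0] * 6)
        f = _fv(Sx=14.0)
        assert sg.differentiation_level(f, model) == pytest.approx((14 - 10) / 2)

    def test_features_at_scaling_midpoint_give_zero(self):
        model = _manual_model(weights=np.ones(6) / np.sqrt(6),
                              loc=[5.0] * 6, scale=[3.0] * 6)
        f = _fv(**{name: 5.0 for name in FEATURE_NAMES})
        assert sg.differentiation_level(f, model) == pytest.approx(0.0)

    def test_unfitted_model_raises_state_error(self):
        model = _manual_model(fitted=False)
        with pytest.raises(ModelStateError):
            sg.differentiation_level(_fv(), model)

    def test_separated_classes_get_dominant_weight_and_full_accuracy(self):
        labeled = _two_class_training()
        model = sg.fit_soil_model(labeled, seed=0, n_restarts=8)
        w = dict(zip(FEATURE_NAMES, np.abs(model.weights)))
        assert w["Sx"] > 0.9
        assert sg.detection_rate(model, labeled) == 1.0
        # grid-search oracle: no random unit direction beats the fit by >5%
        X = np.array([f.as_array() for f, _ in labeled])
        Z = (X - model.feature_loc) / model.feature_scale
        groups = [np.arange(10), np.arange(10, 20)]
        rng = np.random.default_rng(7)
        grid_best = max(
            _separation_objective(v, Z, groups)
            for v in rng.standard_normal((2000, 6))
        )
        assert model.objective >= grid_best * 0.95

    def test_identical_class_distributions_flagged_non_separable(self):
        rng = np.random.default_rng(6)
        pool = [
            _fv(Sx=rng.normal(), Sy=rng.normal(), mean=rng.normal(),
                std=rng.normal(), variance=rng.normal(), kurtosis=rng.normal())
            for _ in range(5)
        ]
        labeled = [(f, c) for c in ("a", "b", "c") for f in pool]
        model = sg.fit_soil_model(labeled, seed=0, n_restarts=4)
        assert not model.separable
        assert model.objective == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_per_class_rejected(self):
        labeled = _two_class_training(n=2)
        with pytest.raises(FitError):
            sg.fit_soil_model(labeled)

    def test_reproducible_given_seed(self):
        labeled = _two_class_training()
        m1 = sg.fit_soil_model(labeled, seed=9, n_restarts=6)
        m2 = sg.fit_soil_model(labeled, seed=9, n_restarts=6)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.thresholds, m2.thresholds)


def _manual_model(weights=None, loc=None, scale=None, thresholds=(1.0, 2.0),
                  classes=("a", "b", "c"), exclusion=(50.0, 8e-4), fitted=True):
    k = len(FEATURE_NAMES)
    return sg.SoilModel(
        classes=list(classes),
        weights=np.array(weights if weights is not None else np.ones(k) / np.sqrt(k)),
        feature_loc=np.array(loc if loc is not None else np.zeros(k)),
        feature_scale=np.array(scale if scale is not None else np.ones(k)),
        class_L_mean={c: float(i) for i, c in enumerate(classes)},
        class_L_std={c: 0.1 for c in classes},
        thresholds=np.array(thresholds),
        exclusion_region=exclusion,
        fitted=fitted,
    )


class TestClassify:
    def test_training_mean_classified_to_own_class(self, soil_features, soil_model):
        for cls in soil_model.classes:
            arrs = np.array([f.as_array() for f, lab in soil_features if lab == cls])
            mean = arrs.mean(axis=0)
            f = sg.FeatureVector(*mean)
            pred, outlier = sg.classify(f, soil_model)
            assert pred == cls
            assert not outlier

    def test_centroid_beyond_x_max_is_outlier_with_class(self):
        model = _manual_model(weights=[1, 0, 0, 0, 0, 0])
        f = _fv(Sx=60.0, Sy=1e-4)  # beyond x_max = 50
        pred, outlier = sg.classify(f, model)
        assert outlier
        assert pred in model.classes

    def test_level_exactly_at_threshold_goes_to_lower_class(self):
        model = _manual_model(weights=[1, 0, 0, 0, 0, 0])
        f = _fv(Sx=1.0, Sy=1e-5)  # L = 1.0 = thresholds[0]
        pred, _ = sg.classify(f, model)
        assert pred == "a"


class TestDetectionRate:
    def test_perfect_predictions_rate_one(self, soil_model, soil_features):
        assert sg.detection_rate(soil_model, soil_features) == 1.0

    def test_permuted_labels_rate_near_chance(self, soil_model, soil_features):
        rng = np.random.default_rng(11)
        labels = [lab for _, lab in soil_features]
        shuffled = list(labels)
        rng.shuffle(shuffled)
        permuted = [(f, lab) for (f, _), lab in zip(soil_features, shuffled)]
        rate = sg.detection_rate(soil_model, permuted)
        assert abs(rate - 1.0 / 6.0) < 0.13  # ~3 sigma of binomial at n=78

    def test_centroid_only_strictly_lower(self, soil_model, centroid_model,
                                          soil_features):
        full = sg.detection_rate(soil_model, soil_features)
        cent = sg.detection_rate(centroid_model, soil_features)
        assert cent < full

    def test_empty_list_undefined(self, soil_model):
        with pytest.raises(UndefinedResultError):
            sg.detection_rate(soil_model, [])


class TestSerialization:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_save_load_round_trip(self, soil_model, tmp_path, suffix):
        path = tmp_path / f"model{suffix}"
        soil_model.save(path)
        back = sg.SoilModel.load(path)
        np.testing.assert_allclose(back.weights, soil_model.weights)
        np.testing.assert_allclose(back.thresholds, soil_model.thresholds)
        assert back.classes == soil_model.classes
        assert back.exclusion_region == pytest.approx(soil_model.exclusion_region)
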