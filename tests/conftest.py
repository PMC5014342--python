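import numpy as np
import pytest

import solegait as sg


@pytest.fixture(scope="session")
def soil_dataset():
    """Shipped six-terrain synthetic strike set: 13 strikes per class, seed 42."""
    recs = sg.simulate_soil_dataset(
        sg.default_soil_profiles(), n_per_class=13, rate=1000.0, seed=42
    )
    return recs


@pytest.fixture(scope="session")
def soil_features(soil_dataset):
    return sg.labelled_features(soil_dataset)


@pytest.fixture(scope="session")
def soil_model(soil_features):
    return sg.fit_soil_model(soil_features, seed=42)


@pytest.fixture(scope="session")
def centroid_model(soil_features):
    return sg.centroid_only_model(soil_features, seed=42)


@pytest.fixture()
def small_recording():
    """A minimal valid 100 Hz recording with one FSR burst."""
    n = 50
    fsr = np.zeros(n)
    fsr[10:20] = 5.0
    accel_z = np.zeros(n)
    accel_z[10:20] = np.sin(np.linspace(0, np.pi, 10))
    return sg.Recording(
        sample_rate=100.0,
        t=np.arange(n) / 100.0,
        accel_x=np.zeros(n),
        accel_y=np.zeros(n),
        accel_z=accel_z,
        fsr={"heel": fsr},
        meta={"subject": "s1"},
    )
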