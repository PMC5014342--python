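"""Classify terrain from heel-strike vibration spectra.

Generates the shipped six-terrain synthetic dataset (13 strikes per class at
1 kHz), fits the weighted-feature level-L classifier, and compares its
held-in detection rate with a centroid-only baseline.  The detection rate is
the fraction of strikes assigned to the correct terrain without being
flagged as centroid outliers; the centroid-only model shows how much the
time-domain features add on terrains whose spectra look alike.
"""

import solegait as sg

recs = sg.simulate_soil_dataset(
    sg.default_soil_profiles(), n_per_class=13, rate=1000.0, seed=42
)
feats = sg.labelled_features(recs)

model = sg.fit_soil_model(feats, seed=42)
baseline = sg.centroid_only_model(feats, seed=42)

print(f"strikes: {len(feats)} across {len(model.classes)} terrains")
print(f"class order on the L axis: {model.classes}")
print(f"weighted-feature detection rate: {sg.detection_rate(model, feats):.3f}")
print(f"centroid-only detection rate:    {sg.detection_rate(baseline, feats):.3f}")
print("-> the weighted level separates terrains the centroid alone confuses",
      "(the two deformable granular classes are spectral twins).")
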