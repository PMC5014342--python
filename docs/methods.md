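# Methods

## Signals and assumptions

`solegait` analyses recordings from a single instrumented insole: tri-axial
acceleration in m/s² (gravity included on the vertical axis), one or more
non-negative FSR load channels in arbitrary sensor units, and an optional
bend channel (carried but not analysed). Streams are assumed uniformly
sampled; timestamps are validated against the declared rate (relative
tolerance 1e-6) and regenerated from the rate when absent. Two regimes are
used: ~1 kHz for heel-strike vibration work and 100 Hz for TUG trials;
`resample` bridges them by linear interpolation.

## Heel-strike windowing and preprocessing

Heel contact is gated on the heel FSR with hysteresis: a window opens above
`onset_frac` (default 0.3) of the per-recording channel maximum and closes
below `release_frac` (default 0.1), so dips between the two thresholds do
not split a contact. The per-recording maximum makes the gate invariant to
unknown sensor scaling. Windows are capped at `max_window_ms` (default
250 ms) to isolate the impact transient.

The vertical-acceleration segment then passes a fixed four-stage chain:
mean removal, zero-padding to the next power of two, multiplication by a
Hamming window of the padded length, and Savitzky–Golay smoothing (defaults
order 3, window 11 samples). Mean removal precedes padding so the pad does
not introduce a step edge. Padding before windowing was chosen so the taper
spans the FFT frame exactly; both orders are defensible and the choice is
fixed here for reproducibility. The chain is linear, so spectra scale with
impact amplitude but keep their shape. Note the Savitzky–Golay defaults act
as a low-pass with appreciable attenuation above roughly 150 Hz at 1 kHz
sampling; informative spectral structure should sit in that passband (the
synthetic terrain profiles do), and the parameters are exposed in config
for sensors that need wider bandwidth.

## Terrain differentiation

Each preprocessed window yields a one-sided magnitude spectrum,
`|FFT|/N` over N/2+1 bins ("mean absolute value" normalisation). The
spectral centroid treats the area under the magnitude curve as a lamina:
`Sx = Σ f·m / Σ m` (Hz), `Sy = Σ m²/2 / Σ m` (magnitude units). A literal
point-mass variant (unit mass at each bin above a floor of 1e-12·max) is
kept as an option, but with a fixed bin grid its Sx degenerates toward the
mid-Nyquist mean, which is why the lamina method is the default. Time-domain
features are the mean, standard deviation, variance (population moments) and
kurtosis (standardised fourth moment; Gaussian → 3, zero-variance windows
flagged and assigned 0) of the preprocessed window.

Features are standardised to zero mean/unit variance over the training set
— they differ by orders of magnitude, and the weight optimisation would
otherwise be dominated by scale. Unit-norm weights maximise

    J(w) = min over class pairs |mean_L(c1) − mean_L(c2)|
                                / (std_L(c1) + std_L(c2) + 1e-6),

a minimax Fisher-type criterion that operationalises "spread the class
levels apart". The optimiser is deterministic given the seed: candidate
directions are the coordinate axes, the leading multiclass Fisher (LDA)
direction, and the best of a screened pool of 200·`n_restarts` random unit
vectors; the top `n_restarts` (default 24) candidates are each polished by
Nelder–Mead. Weights under 5% of the norm are zeroed afterwards (a cheap
stand-in for subset selection) and the sign is normalised so the dominant
component is positive. Classes are ordered by mean L; thresholds sit at
midpoints of adjacent class means, ties at a threshold going to the lower
class. A fit whose objective is ≈ 0 is flagged non-separable.

The exclusion rectangle `[0, x_max] × [0, y_max]` in centroid space flags
outlier strikes (erratic responses of deformable terrain). When fitted from
data it is the bounding box of the training centroids scaled by a 1.5
margin; fixed bounds can be forced through `soil.exclusion_x_max/y_max`,
and an unfitted model defaults to (50, 8e-4). The detection rate counts a
strike as detected only if it is classified correctly *and* not flagged as
an outlier, over all strikes presented.

## TUG segmentation and gait parameters

Total FSR load segments the trial: the standing-load threshold is half the
median *loaded* value (median over samples in the upper half of the
channel's range), and trial start/end are the first/last crossings
sustained ≥ 0.5 s. Steps are peaks of the mean-removed, 10 Hz low-passed
acceleration magnitude, at least 0.3 s apart with prominence ≥ 0.5 of the
segment standard deviation. The accelerometer count is cross-checked
against FSR burst counts (median-filter detrended load, same peak rules);
a disagreement beyond 20% of the FSR count switches the step source to the
FSR with a logged warning. The turn is the contiguous run of step intervals
nearest the temporal midpoint of the walking portion whose interval exceeds
1.3× the median step interval — turning slows stepping, and the out-and-back
design puts it mid-trial.

Instantaneous cadence is 60/interval (steps/min). Strides pair consecutive
steps (`gait.single_foot` treats each detected interval as a full stride
when only one foot registers). Stride length uses the mean rectified,
mean-removed stride acceleration, `SL = 0.98·(Σ|a_i|/N)^(1/3)`;
rectification is required because the signed mean of an oscillatory gait
signal is ≈ 0. Walking speed is accumulated stride length over the walking
time. Step intervals and strides overlapping the detected turn are excluded
from the cadence and stride statistics: turn intervals exceed the walking
median by construction and would otherwise conflate turning style with gait
variability — the variability the risk index targets is steady-state
walking variability.

CVs use the sample (n−1) standard deviation, appropriate at the small
per-trial n. The risk index is `Risk = α(CV_cad + CV_SL)` with
`α = alpha_c / speed` and `alpha_c = 1` by default; α is deliberately a
config knob (`risk.alpha_c`) since it is a clinician-tunable sensitivity.
TUG time < 10 s maps to `normal`, > 16 s to `increased_risk`, the closed
interval in between to `intermediate`.

## Cueing

Baseline cadence is the mean of per-trial mean cadences over at least two
reference-terrain trials. The cue rate is 10% above baseline
(`cue.uplift`), delivered as 50 ms pulses at uniform 60/f spacing starting
at t = 0; rates whose inter-pulse interval does not exceed the pulse width
are rejected. Cueing activates only when the current risk strictly exceeds
the reference risk. The PWM carrier that drives the motor is hardware and
is abstracted to this on/off timeline.

## Synthetic data: what it emulates and what it does not

**Strikes.** A terrain is a set of damped resonances: the waveform is
`Σ_k exp(−ζ_k ω_k τ)·sin(ω_k τ)` plus white grain noise, gated by a
half-sine contact envelope, with the ring onset placed 30% into the contact
window (the FSR closes before peak impact, and a front-loaded transient
would otherwise be suppressed by the Hamming taper downstream).
`freq_jitter_hz` wanders the resonance per strike, emulating the
unpredictable effective stiffness of deformable terrain. `phase="diffuse"`
randomises the spectral phase of the finished waveform — grain
reverberation that smears the impact energy across the contact — leaving
the magnitude spectrum untouched.

The shipped six-terrain library places four low-noise terrains at
resonances 145/105/65/25 Hz (harder → higher and less damped, ≥ 40 Hz
apart, inside the preprocessing passband) and models the two deformable
granular terrains as *spectral twins*: the same heavily damped 85 Hz
response with 5 Hz per-strike wander, stone dust keeping the coherent
fracture transient and sand dispersed. Their centroid coordinates are
therefore statistically coincident while time-domain kurtosis (≈ 19 vs ≈ 5
after preprocessing) and signal power separate them sharply. This geometry
reproduces, by construction, the qualitative finding the terrain classifier
exists to demonstrate: centroid-only classification fails on deformable
granular terrain, the weighted feature level does not. Absolute centroid
coordinates of real terrains are not reproduced (no spectra are published
to match), so the exclusion rectangle is fitted from data rather than fixed.

**TUG trials.** Load ramps linearly over the sit-to-stand and stand-to-sit
phases (defaults 1.2 s each for the healthy profile) between a seated value
and a standing value, staying high through walking and the turn; each step
adds a half-sine stance bump on the FSR and a fixed-shape, zero-mean
one-cycle sine burst on the vertical acceleration riding on gravity. Step
intervals are drawn `Normal(60/cadence, CV)` and snapped to the sample grid
(so zero nominal variability survives detection); per-stride burst
amplitudes invert the SL relation so the trial carries known stride
lengths; the turn is a step-free gap (default 1.2 s) at the trial midpoint.
Ground truth records phase times, step peak times and stride lengths.

The generator emulates the *statistical* structure the pipeline estimates
— phase boundaries, step counts, cadence and stride variability — not
biomechanics: no double support, no swing-phase unloading (the load
envelope stays high while walking; segmentation relies on that), no
freezing-of-gait episodes, no soft-tissue artefacts. Passing tests
therefore demonstrate correct recovery of the model's quantities under
clean conditions and say nothing about robustness to real-world sensor
artefacts.

**Problem sizes.** The shipped terrain experiment is 6 classes × 13
strikes (matching the single-walker protocol the device was designed
around); parameter-recovery checks use 50 seeded trials of 20 strides at
nominal CV 5%, where both CVs are recovered with mean absolute error well
under 1 percentage point.

## Numerical choices and edge cases

* Strike windows shorter than the Savitzky–Golay window, even windows, or
  window ≤ order raise parameter errors rather than silently adjusting.
* All-zero spectra make the centroid undefined (error); zero-variance
  windows flag kurtosis as degenerate instead of dividing by zero.
* Detection thresholds (FSR fractions, peak prominence) are relative to
  per-recording statistics, never absolute sensor units.
* `fit_soil_model` requires ≥ 2 classes and ≥ 3 strikes per class; class
  thresholds of a non-separable fit may coincide and the model is flagged
  rather than rejected.
* Every stochastic routine takes an explicit integer seed;
  fits and generators are reproducible bit-for-bit given (data, seed).

## Known limitations

* The single-axis level L is a linear projection; terrain sets whose
  feature geometry is not separable on one axis need the richer classifiers
  deliberately left out of scope.
* Stride length's cube-root relation is a population-calibrated
  approximation; its constant (0.98) is not re-calibrated per subject.
* Turning detection assumes one out-and-back walk with a single turn; mid
  walk hesitations longer than 1.3× the median step interval near the
  midpoint would be mistaken for the turn.
* With one instrumented foot the contralateral step train is unobserved;
  cadence and stride statistics then describe the instrumented side only.
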