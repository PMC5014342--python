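"""Build a rhythmic vibrotactile cue schedule from baseline walking trials.

Estimates the preferred cadence from two baseline trials, raises it by 10%,
and emits the 50 ms pulse train a vibrotactile insole driver would realise.
"""

import solegait as sg

baseline_recs = [sg.simulate_tug(sg.healthy_profile(), seed=s) for s in (0, 1)]
gait = []
for rec, _ in baseline_recs:
    phases = sg.segment_tug(rec)
    steps = sg.detect_steps(rec, phases)
    gait.append(sg.gait_params(steps, rec, phases))

cadence = sg.baseline_cadence(gait)
freq = sg.cue_frequency(cadence)
schedule = sg.generate_schedule(freq, duration=10.0)

print(f"baseline cadence: {cadence:.1f} steps/min (mean of 2 trials)")
print(f"cue frequency:    {freq:.1f} pulses/min (+10%)")
print(f"pulse train over 10 s: {len(schedule.pulse_times)} pulses of "
      f"{schedule.pulse_duration * 1000:.0f} ms")
print("first five onsets (s):", [round(float(t), 3) for t in schedule.pulse_times[:5]])
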