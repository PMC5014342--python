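"""Score a Timed Up and Go trial and decide whether to cue.

Simulates two baseline trials on the reference terrain plus one impaired
trial, then runs the full pipeline: phase segmentation, step detection,
gait parameters, the risk index Risk = (CV_cad + CV_SL) / speed, the TUG
mobility category, and the cue decision (cue when the trial risk exceeds
the baseline reference risk).
"""

import json

import solegait as sg

baselines = [sg.simulate_tug(sg.healthy_profile(), seed=s)[0] for s in (0, 1)]
trial, _ = sg.simulate_tug(sg.impaired_profile(), seed=2)

report = sg.run_tug_pipeline(trial, baselines)

print(json.dumps(report, indent=2, sort_keys=True))
print()
t = report["trial"]
print(f"TUG time {t['phases']['tug_time_s']:.1f} s -> category {t['category']!r}")
print(f"risk {t['risk']['risk_pct']:.1f} vs baseline "
      f"{report['baseline']['reference_risk_pct']:.1f} "
      f"-> cue active: {report['cue']['active']}")
print(f"cue rate: {report['cue']['frequency_ppm']:.1f} pulses/min "
      "(10% above baseline cadence), 50 ms pulses")
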