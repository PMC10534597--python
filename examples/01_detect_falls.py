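"""Detect multiple falls in one continuous synthetic trace.

Generates a 100 Hz trace containing seven canonical falls (dip below
6.5 m/s², impact spike, settling at g) separated by rest, runs the
two-stage pipeline at the default thresholds, and prints each accepted
fall's time range and peak.
"""

from accelfall import run_pipeline
from accelfall.synthetic import fall_scenario, generate

series, truth = generate(fall_scenario(n_falls=7, noise_sd=0.2, seed=42))
report = run_pipeline(series)

print(f"{len(series)} samples at {series.frequency_hz:.0f} Hz, "
      f"{len(truth)} scripted falls, {report.n_candidates} candidates, "
      f"{len(report.accepted)} accepted")
for i, fall in enumerate(report.accepted, 1):
    print(f"fall {i}: {fall.start_time_s:6.2f} s -> {fall.end_time_s:6.2f} s, "
          f"peak {fall.peak_magnitude:5.1f} m/s^2")
# Each line is one validated fall: the start is the onset dip, the end the
# impact spike, and the peak the largest magnitude inside that range.
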