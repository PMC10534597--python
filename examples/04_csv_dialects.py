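"""Round-trip a trace through the dataset CSV dialects.

Writes a synthetic trace as a KFall-style per-trial CSV (acceleration in g,
time column in seconds), reads it back with unit conversion, detects the
fall, and writes the detections file the CLI produces.
"""

import tempfile
from pathlib import Path

from accelfall import run_pipeline
from accelfall.dataset_io import read_trial_csv, write_detections, write_trial_csv
from accelfall.synthetic import fall_scenario, generate

series, truth = generate(fall_scenario(noise_sd=0.2, seed=3))
with tempfile.TemporaryDirectory() as d:
    trial_csv = Path(d) / "trial.csv"
    write_trial_csv(series, trial_csv, dialect="kfall")
    trial = read_trial_csv(trial_csv, dialect="kfall", label="fall")
    print(f"read {len(trial.series)} samples; "
          f"x[0] back in m/s^2: {trial.series.x[0]:.4f}")

    report = run_pipeline(trial.series)
    det_csv = Path(d) / "detections.csv"
    write_detections(report, det_csv, trial_id=trial.trial_id)
    print(det_csv.read_text().strip())
# The detections file has one row per accepted fall: identifiers, start/end
# in seconds and entry units, and the impact peak magnitude in m/s^2.
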