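# accelfall

Two-stage threshold-based human fall detection for tri-axial accelerometer
streams. Falls are the second most common cause of accidental death and the
leading one among the elderly; wearable accelerometers make continuous
monitoring feasible, but learned classifiers need fixed input shapes and
training data. `accelfall` implements the alternative: a low-complexity
heuristic detector that works on a stream of any length, at any sampling
rate, without knowing how the sensor is oriented, and that reports the
concrete time range of every fall it finds.

## The method

The only orientation-free scalar available from a bare accelerometer is the
sum vector magnitude

    M_n = sqrt(x_n² + y_n² + z_n²)     [m/s²]

which rests near g = 9.80665 m/s² when the wearer is still. Time is
re-expressed as a frequency-normalised pseudo-timestamp, the *entry*:

    entry_0 = 0
    entry_n = (t_n − t_{n−1})/10 + entry_{n−1} + 100/f

with `t` in seconds and `f` the nominal rate in Hz, so ~100 entry units
correspond to about one second at any sampling frequency and every temporal
threshold is rate-independent.

A fall produces a dip in `M` below `min_limit` (the body drops), then within
about a second an impact spike above `max_limit`, then settling back at g.

**Stage one (detection)** classifies magnitudes as low (`< min_limit`,
default 6.5 m/s²) or high (`> max_limit`, default adaptive:
`max(mean(M), 20) + 10`), clusters each class into extreme sets split
wherever consecutive entries differ by more than `sub_1` (50 ≈ 0.5 s), and
connects every low set to every high set whose finish-high minus start-low
entry span is positive and at most `fall_duration` (105 ≈ 1 s). Each
connection is a candidate fall.

**Stage two (validation)** applies three checks: (1) when candidates share
an extreme set, only the shortest survives; (2) candidates longer than
`fall_limitation` (85) are shrunk to the low nearest the impact, or rejected;
(3) a candidate is accepted only if the magnitudes in the window after it
settle near g (low mean deviation and standard deviation), **or** its peak
strictly dominates every magnitude above `max_limit_2` within `dist_1`/
`dist_2` (100/100) entries around it. Daily activities with fall-like
fragments — jumps, stumbles, sitting down hard — mostly fail both.

Evaluation follows the standard confusion accounting with the
multiple-detection rule (every detection beyond the first on a fall trial is
a false positive) and reports accuracy, sensitivity, specificity and
precision.

## Worked example

```bash
python examples/01_detect_falls.py
```

```
2500 samples at 100 Hz, 7 scripted falls, 7 candidates, 7 accepted
fall 1:   2.00 s ->   2.73 s, peak  54.4 m/s^2
fall 2:   5.00 s ->   5.75 s, peak  46.2 m/s^2
fall 3:   8.00 s ->   8.70 s, peak  43.7 m/s^2
fall 4:  11.00 s ->  11.26 s, peak  52.1 m/s^2
fall 5:  14.00 s ->  14.36 s, peak  38.4 m/s^2
fall 6:  17.00 s ->  17.47 s, peak  55.8 m/s^2
fall 7:  20.00 s ->  20.31 s, peak  35.3 m/s^2
```

One continuous noisy trace contains seven scripted falls; the pipeline finds
all seven candidates and validates all seven, each line giving the onset dip
time, the impact time, and the peak impact magnitude. The other examples
score a labelled synthetic suite (`02`), sweep `fall_duration` and print the
ROC trade-off (`03`), and round-trip the CSV dataset dialects (`04`).

The same pipeline is available from the shell:

```bash
accelfall simulate --scenario fall --n-falls 3 --seed 11 --out sim/
accelfall detect --input sim/trace.csv --dialect kfall --out detections.csv
accelfall evaluate --detections detections.csv --truth sim/ground_truth.csv
```

Dataset dialects are provided for per-trial files with acceleration in g and
a time column (KFall-style, converted with 9.807 m/s² per g), per-trial
files without timestamps (UR-style, synthesised at 60 Hz), and continuous
per-subject labelled streams (MMsys-style, synthesised at 100 Hz).

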