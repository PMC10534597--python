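# Methods

## Model and assumptions

The detector operates on the sum vector magnitude
`M_n = sqrt(x_n² + y_n² + z_n²)` of a tri-axial accelerometer. The single
modelling assumption is the fall morphology: a short interval of magnitudes
well below gravity (the body in partial free fall), followed within roughly
one second by an impact spike well above gravity, after which the signal
settles near g because the person is on the ground. No filtering or
denoising is applied to the raw signal; the detector keys on runs of
extremes, so isolated spurious samples rarely change a verdict (a lone low
or high forms a singleton set that connects to nothing).

Time is handled through the *entry* recursion
`entry_n = (t_n − t_{n−1})/10 + entry_{n−1} + 100/f` with `entry_0 = 0`.
With timestamps in **seconds**, entries advance by ≈ 100 units per second of
signal at any nominal rate (100.1 at an ideal 100 Hz, i.e. 100 entry units ≈
0.999 s), which is what makes one set of temporal thresholds valid for 60 Hz
and 100 Hz sensors alike. Seconds are the only unit choice under which the
calibrations used throughout (`sub_1 = 50 ≈ 0.5 s`, `fall_duration ≈ 1 s`)
hold, so the package fixes it; the `Δt/10` term is kept exactly as stated,
acting as a small correction for timestamp jitter and gaps. Timestamps
synthesised for datasets without a time column are `i / f` seconds.

## Thresholds

| name | default | unit | role |
|---|---|---|---|
| `min_limit` | 6.5 | m/s² | magnitudes strictly below are low |
| `max_limit` | `max(mean(M), 20) + 10` | m/s² | magnitudes strictly above are high |
| `sub_1` | 50 | entries | gap that splits a run of extremes into two sets |
| `fall_duration` | 105 | entries | max finish-high − start-low span of a candidate |
| `fall_limitation` | 85 | entries | span above which a candidate is long |
| `dist_1`, `dist_2` | 100, 100 | entries | neighbourhood searched for rival peaks |
| `max_limit_2` | `= max_limit` | m/s² | high threshold for rival peaks |

`max_limit` is resolved **once over the entire input series**, adapting the
detector to the overall activity level of the trace; there is no windowed
variant. `max_limit_2` values below `max_limit` would not change any
decision (rivals below the high threshold never defeat a fall peak), so the
default keeps equality. All comparisons are strict for the low/high
classification, inclusive for the span tests (`span ≤ fall_duration` to
connect; split on `gap > sub_1`).

The post-fall stability check ("the magnitudes after the fall stay close to
g") needs three quantities the method's description leaves qualitative. The
package exposes them in the configuration rather than hard-coding them:
`stability_window` (default: reuse `dist_2`, i.e. ≈ 1 s, instead of
inventing a ninth temporal constant), `mean_tol = 1.5 m/s²` and
`std_tol = 2.0 m/s²`. These two tolerances are this package's own defaults —
chosen so that quiet lying (|mean − g| well under 1 m/s² even with sensor
noise) passes and continued activity (oscillations of several m/s²) fails —
and tests reference them only through the configuration.

## Pipeline semantics and tie-breaks

* **Candidate span**: start = first member of the low set, end = last member
  of the high set ("start-low", "finish-high"). A connection requires the
  low set to precede the high set — every documented fall pattern shows lows
  then highs, and accepting the reverse would invent a morphology with no
  physical reading.
* **Shared extremes**: the survivor set is computed as a deterministic
  fixpoint — repeatedly keep the globally shortest remaining candidate (ties:
  earlier start, then earlier end) and drop everything sharing a set with
  it. Ties cannot arise from a strictly increasing entry sequence, but the
  rule keeps output ordering deterministic regardless.
* **Long-fall shrink**: among classified lows strictly inside the candidate
  whose entry brings the span within `fall_limitation`, the start moves to
  the one with the largest entry, i.e. the low closest to the impact; the
  peak is recomputed over the shrunk span. One written description of this
  check reads with the opposite inequality ("recognises a true event when
  the span is greater than `fall_limitation`"); the implementation follows
  the threshold table's definition — a span *greater* than the limit marks
  the fall as long and triggers shrink-or-reject — which is the only reading
  consistent with the illustrated examples.
* **Peak dominance** compares the fall's peak against *raw samples* above
  `max_limit_2` in the neighbourhood (`[start − dist_1, start)` and
  `(end, end + dist_2]`, excluding the fall's own span), the stricter of the
  two possible readings (the alternative — comparing only against clustered
  high-set peaks — can never reject more). The comparison is strict: an
  equal rival defeats the assumption.
* **Empty stability window** (fall ending at the end of the series) counts
  as insufficient evidence: assumption A is false, B may still accept.
* Accepted falls are reported sorted by (start entry, end entry); the
  standard deviation in the stability check is the population form (ddof 0).

## Synthetic data

The generator scripts a magnitude profile and distributes each sample over
x/y/z via a unit vector (one random direction per event, gravity along z at
rest), so `sqrt(x²+y²+z²)` reproduces the scripted magnitude to machine
precision and rotation invariance can be tested exactly. The canonical fall
draws dip magnitude ∈ [1, 5.5] m/s² for 0.1–0.3 s, a dip-to-impact delay of
0.05–0.6 s, and a spike of 35–60 m/s² for 1–3 samples, followed by ≥ 1.5 s
of settling — by construction within `fall_duration` of the default
thresholds and recoverable by the shrink stage when the span exceeds
`fall_limitation`. Confounders: walking/jogging sinusoids bounded strictly
inside the (low, high) band; a gentle-jump morphology (impact-like spike with
a smaller secondary peak and *no* qualifying dip); a sub-threshold
sit-and-overshoot bump. Magnitude noise is i.i.d. Gaussian (default
σ = 0.2 m/s²) applied before axis decomposition.

What the generator does **not** emulate: genuine free-fall dynamics and body
rotation during descent, sensor-axis gravity tracking, drift or saturation,
and the hard real-data confounders (stumbles, collapses into chairs) whose
dips and spikes genuinely interleave with falls. Passing the synthetic suite
therefore establishes that the implementation realises the stated decision
rules and recovers its own canonical pattern robustly — not that the
detector reaches any particular performance on recorded human data; the
dataset readers exist so that real corpora can be evaluated when available.

## Verification strategy

Every pipeline stage is checked against an independent pure-Python
brute-force reference (exhaustive enumeration of low/high pairings and
literal application of the three validation rules) on thousands of random
series with randomised thresholds; the acceptance script recomputes this
agreement rate along with detection/false-positive rates on freshly
generated scenarios (25 noiseless falls, 100 noisy falls, 40 rest traces,
a 7-fall trace, 300 random-series cross-checks, and a 100-trial mixed
suite — sizes chosen to keep the script fast while leaving each rate
estimate meaningful). Properties asserted as invariants: rotation and
time-translation invariance, entry-rate calibration, candidate spans never
exceeding `fall_duration`, conservation (validation never creates a fall),
idempotence of validation, and monotonicity of the acceptance checks under
tightened tolerances.

## Known limitations

* Whole-trial processing: the adaptive `max_limit` needs the full series, so
  the pipeline is not streaming; splitting a stream is safe only with a
  fixed `max_limit` and cuts far from any extreme.
* Activities whose magnitude pattern embeds a genuine dip-then-spike within
  about a second (hard stumbles, collapsing onto a chair) are accepted by
  design; on real corpora these are the dominant false-positive sources.
* Continuous low-magnitude activity (e.g. jogging) can merge a fall's dip
  into a long low set whose start is too far from the impact, losing the
  connection; lowering `sub_1` recovers such falls at a substantial
  specificity cost — exposed as configuration, not a default.
* The stability tolerances are package-chosen constants (see above), not
  method-prescribed values.
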