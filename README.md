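# timebisect

Simulation and analysis pipeline for **temporal-bisection EEG experiments
under ensemble temporal contexts**: psychometric PSE/JND estimation, and
extraction of the timing-related ERP components (CNV climbing rate and
peak, offset P2, LPCt, CNV crossing latency), with group-level statistics.

## The problem

In a temporal bisection task, a listener judges whether a probe duration is
closer to a memorized *short* (400 ms) or *long* (1600 ms) anchor.  Although
the anchors never change, the **ensemble** of probe durations within a
session — their spacing (positively vs negatively skewed sets, PS/NS) or
their sampling frequencies (descending vs ascending counts, DF/AF) — biases
judgment: the bisection point (PSE) migrates toward the session's
frequency-weighted ensemble mean.  On frontocentral EEG, the slow climbing
negativity preceding the decision (the contingent negative variation, CNV)
and the post-offset/cue positivities (offset P2, LPCt) carry signatures of
this contextual modulation.

Group results from real recordings cannot be reproduced at desk scale, so
the package is built around a **synthetic generator with known ground
truth**: every analysis stage is validated by parameter recovery.

## What the package computes

* **Designs** (`timebisect.designs`) — the four printed experiment arms and
  their trial schedules.  PS = [400, 504, 636, 800, 1008, 1270, 1600] ms,
  NS = [400, 730, 992, 1200, 1366, 1496, 1600] ms (48 repetitions each,
  336 trials in 6 blocks of 56); the equally spaced set
  [400, 600, …, 1600] ms sampled [12, 24, 36, 48, 60, 72, 84] times (AF) or
  the reverse (DF), with a 300-ms gap before the response cue.
* **Behavior** — responses are Bernoulli draws from a lapse-augmented
  logistic; the per-participant threshold is pulled toward the context's
  ensemble mean with weight *w*:
  `alpha = (1 - w)·800 + w·ensemble_mean + delta_p`.
  Fitting is by maximum likelihood; **PSE** is the 50% threshold and
  **JND** = threshold(75%) − threshold(50%) (= β·ln 3 at zero lapse).
* **Epochs** — a single frontocentral virtual channel: onset N1/P2
  complex, a CNV ramp (context-dependent slope in μV/s) clipped at a
  plateau and held to the stimulus offset, a linear resolution ramp, an
  offset-locked P2 growing with duration, a cue-locked LPCt shrinking with
  duration (hinged at the bisection point), plus white and 1/f noise.
* **ERP measures** — CNV climbing rate (OLS slope over 250–650 ms), peak
  latency/amplitude (±5 ms mean around the extremum), mean amplitude over
  [250, 250 + D] ms, negative-to-positive crossing latency after 650 ms,
  offset-P2 and LPCt peaks and windowed means, each after its own
  per-trial baseline (onset −200–0 ms; offset ±50 ms; cue ±50 ms).
* **Statistics** — paired t-tests with JZS Bayes factors (Cauchy prior,
  scale √2/2), Pearson correlations, and REML random-intercept mixed
  models (Duration in seconds; between-within small-sample df).

## Worked example

```python
from timebisect.pipeline import RunConfig, run_experiment

report = run_experiment(RunConfig(experiment_id="exp1", n_participants=19, seed=1))
print(report.summary_text)
```

```
Experiment 1 (spacing)  n = 19
Context       Climbing rate (uV/s)     Peak latency (ms)   Peak amplitude (uV)   Mean amplitude (uV)              PSE (ms)              JND (ms)
Short (PS)           -23.6 +/- 0.2         689.9 +/- 9.5          -8.5 +/- 0.0        -4.97 +/- 0.03        867.7 +/- 19.6         122.9 +/- 5.9
Long (NS)            -20.7 +/- 0.3        870.8 +/- 14.7          -9.3 +/- 0.0        -5.69 +/- 0.03        983.2 +/- 16.2         122.6 +/- 4.0
```

The short (PS) context yields a lower PSE than the long (NS) context — the
bisection point has moved toward each session's ensemble mean (the
programmed pull is *w* = 0.5 of the 223.7-ms ensemble-mean gap, and the
fitted group difference of ≈ −115 ms recovers it) — and a steeper
(more negative) CNV climbing rate, matching the programmed −23 vs −20 μV/s.
The first rows of `report.group_stats`:

```
                   measure      test     term  estimate  statistic  df        p     bf10
                    pse_ms  paired_t  PS - NS      -115      -12.8  18  1.7e-10 5.49e+07
                    jnd_ms  paired_t  PS - NS     0.293     0.0588  18    0.954    0.238
cnv_climbing_rate_uv_per_s  paired_t  PS - NS     -2.97      -21.8  18 2.15e-14 2.47e+11
```

The same pipeline is scriptable from the shell:

```sh
timebisect dump-defaults > config.txt
timebisect run-all --config config.txt --out out/ --seed 1
timebisect fit-behavior --trials out/trials.csv --out out/fits.csv
```

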