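# Methods

## Scope and design

The package re-implements, as a tested pipeline over synthetic data, the
complete analysis of a two-experiment temporal-bisection EEG design: the
behavioral psychometric analysis (PSE/JND under ensemble-context
manipulations of stimulus spacing and sample frequency) and the ERP
component measures defined on a frontocentral virtual channel (CNV climbing
rate, peak latency/amplitude, mean amplitude, crossing latency; offset P2;
LPCt).  Raw-EEG preprocessing (referencing, filtering, ICA) is out of
scope: the generator produces clean-plus-modeled-noise epochs directly.

## Behavioral model

For participant *p* in context *c* the probability of a "long" response to
duration *D* (ms) is

    P(long | D) = λ/2 + (1 − λ) · logistic((D − α_pc) / β_p)
    α_pc = (1 − w)·α₀ + w·EM(c) + δ_p

with EM(c) the frequency-weighted ensemble mean of the context's duration
multiset, α₀ = √(400·1600) = 800 ms (the geometric mean of the anchors,
the classical context-free bisection point), δ_p ~ N(0, σ_α) a participant
trait shared across contexts, and β_p ~ N(β₀, σ_β) truncated at 20 ms.
Thresholds are clipped to stay strictly inside the anchor range.

Defaults (the generator's study conditions): w = 0.5, β₀ = 110 ms
(JND ≈ 121 ms), λ = 0, σ_α = 60 ms, σ_β = 15 ms.  With w = 0.5 the
programmed PS/NS threshold gap is 0.5 × 223.71 ≈ 112 ms; the sign
PS < NS (and DF < AF) is the behavioral effect every recovery test keys on.

**Fitting.**  Maximum likelihood on the per-duration Bernoulli counts,
Nelder–Mead from four deterministic starts with α spanning the duration
range (20/40/60/80%) and log β started at log(range/6); ties resolve to
the lowest NLL, then the smallest β.  λ is fixed at 0 by default (a free
λ ≤ 0.06 sits behind a flag; which convention the original fits used is
not documented, so both modes exist and the default is the simpler one).
PSE and JND are obtained by bracketed root-finding on the fitted curve
rather than the closed form, so the free-λ variant needs no special
casing; the closed form (PSE = α, JND = β·ln 3) serves as the test oracle.
Cells with a single response category are flagged non-identifiable, never
extrapolated.

## ERP waveform model

One virtual channel stands for the mean of the six frontocentral
electrodes; multi-channel simulation would add nothing testable.  The grid
is [−300, 2800] ms at 1000 Hz, covering the longest trial
(1600 ms + 300 ms gap + LPCt window).  A trial's template is the sum of

1. onset N1 and P2 Gaussians (−4 μV at 90 ± 18 ms; +5 μV at 180 ± 25 ms —
   narrow enough that their tails are negligible beyond 250 ms);
2. a CNV ramp starting at 250 ms with context slope s (μV/s), clipped at a
   plateau of −10 μV and held until stimulus offset; per-participant slope
   offsets ~ N(0, 1.5 μV/s) are shared across contexts (clipped ≤ −5).
   Default slopes: PS −23, NS −20, DF −19, AF −17 μV/s;
3. a linear resolution ramp back to baseline over 300 ms after offset (the
   return-to-baseline dynamics are not quantified anywhere; a linear ramp
   is a deliberate modeling choice, flagged as such);
4. an offset-locked P2 Gaussian (σ = 30 ms), amplitude 3.5 + 2.9·D_s μV,
   latency 345 − 78·D_s ms after offset;
5. a cue-locked LPCt Gaussian (σ = 70 ms), amplitude
   a₀ + a₁·max(0, L − D)/1000 with a₀ = 3 μV, a₁ = 6 μV/s and the hinge
   L = 900 ms near the programmed bisection point (amplitude falls with
   duration, then levels off), latency 330 − 77·D_s ms after the cue.

The template is identically 0 for t ≤ 0.  Noise is white Gaussian
(σ = 3 μV per sample) plus 1/f^χ noise (χ = 1, 2 μV per trial, generated
by spectral shaping with per-trial SD normalization).  The white+pink
defaults sit inside the ≤ 5 μV envelope the recovery properties assume.
Amplitude-scale defaults were chosen once so that group means land in a
plausible neighborhood of real grand averages; they are generator
conditions, not fitted quantities.

## ERP measures

All measures run on participant-level condition averages (participant ×
context × duration), after the per-trial baseline appropriate to the
component: CNV — 200 ms before onset; offset P2 — offset ± 50 ms; LPCt —
cue ± 50 ms.  Windows are closed intervals on the 1-ms grid.

* climbing rate: OLS slope over [250, 650] ms, in μV/s;
* CNV peak: most negative sample in [0, 1600] ms; amplitude = mean over
  ±5 ms around the peak; ties resolve to the earliest sample; extrema on a
  window edge (or a clipped ±5 ms window) are flagged, not dropped;
* CNV mean amplitude: mean over [250, 250 + D] ms.  This window extends
  past the stimulus offset for every duration; it is implemented literally;
* crossing latency: first pair v(tᵢ) < 0 ≤ v(tᵢ₊₁) with tᵢ ≥ 650 ms,
  refined by linear interpolation; missing (NaN) if no crossing occurs —
  a value, not an error;
* offset P2: most positive sample in [0, 500] ms after offset; mean over
  [140, 300] ms after offset;
* LPCt: most positive sample in [0, 500] ms after the cue; mean over
  [300, 500] ms after *offset* while its baseline is cue-locked — the two
  conventions are deliberately mixed, matching the component definitions.

**Aggregation for group summaries.**  The per-context climbing rate is the
per-participant mean over durations ≥ 650 ms, so the regression window
lies fully within the stimulus.  For shorter probes the window contains
the post-offset resolution/P2 complex and the early ramp is disrupted (the
immature-CNV problem for sub-600-ms probes); their per-duration rates stay
in the feature table but are excluded from the slope summaries and the
recovery checks.

**Identifiability of the CNV peak latency.**  The modeled CNV holds a flat
plateau until offset, so for durations long enough to reach the plateau
the argmin under any noise is uniformly distributed across the plateau —
peak latency is not identifiable there.  The latency-recovery property is
therefore tested on durations that end before the plateau is reached
(offset-locked, V-shaped peak) at low noise within the stated envelope.
At realistic noise the latency estimator scatters on the order of tens of
milliseconds, consistent with the large between-participant variability
this measure shows on real data; passing tests demonstrate correctness of
the extraction, not clinical precision of latency estimates.

## Statistics

* Paired t-tests with two-sided p, t-quantile 95% CI, and a JZS Bayes
  factor: the Cauchy effect-size prior (scale r = √2/2 by default — the
  conventional default; the prior is a config knob since no particular
  scale is canonical) is integrated via the inverse-gamma mixture with
  adaptive quadrature at tolerance 1e-8, in log space so large |t| cannot
  underflow; non-convergent quadrature raises.
* Pearson correlation with t-based p (df = n − 2); its Bayes factor uses
  the default Jeffreys correlation test via pingouin.
* Mixed models: REML random-intercept fits (statsmodels MixedLM) of
  response ~ Context × Duration, Duration rescaled to seconds so
  coefficients print in μV/s.  Small-sample p-values use a between-within
  (nlme-style) denominator df, n_obs − n_groups − (k − 1), recorded in the
  result's `df_method`; a full Kenward–Roger routine is out of proportion
  here, and the approximation's size is verified by simulation (type-I
  error of the Context test ≈ 0.04–0.06 at nominal 0.05 over 400 null
  simulations at n = 19).  Singular fits (variance at the boundary) and
  constant-response degeneracies are reported in `notes`.

The LMM calibration generator (`simulate_amplitude_table`) draws one
amplitude per participant × context × duration with intercept 0.2 μV,
duration slope −1.5 μV/s, participant SD 1.0 μV and residual SD 1.0 μV —
magnitudes in the range of frontocentral mean-amplitude data.

## Problem sizes and numerical choices

Recovery checks run at the study's printed scale: 19 participants,
336 trials per context, 48 trials per duration cell (experiment 1).  The
ERP recovery suite uses 12 (tests) / 20 (acceptance script) independent
seeded runs; behavioral ordering uses 200 simulated participant pairs;
mixed-model calibration uses 400 null simulations.  All randomness flows
from integer seeds through `numpy.random.SeedSequence`, so every table is
bit-reproducible under (config, seed).  Optimizer tolerances: Nelder–Mead
xatol 1e-6 / fatol 1e-10; root-finding xtol 1e-9; quadrature 1e-8.

Block bookkeeping: sessions partition into 6 equal blocks (56 trials for
the printed designs) purely for bookkeeping; whether the frequency
manipulation balanced counts within blocks is unknown, so only session
totals are enforced.  Schedules are unconstrained random permutations (no
run-length limits).  Session order is carried as a participant attribute
but affects no computation.

## What the generator does and does not emulate

It emulates the statistical structure the analysis assumes: logistic
choice behavior with an ensemble-mean pull, component morphology with
duration- and context-dependent parameters, white + 1/f noise, and
participant-level heterogeneity.  It does **not** emulate volume
conduction, topographies, artifacts (blinks, muscle), non-stationary
noise, trial-order effects (fatigue, sequential dependencies), or
violations of the logistic form.  Passing recovery tests therefore show
that the pipeline measures what it claims to measure under the assumed
data-generating process — not that real EEG satisfies those assumptions.

## Known limitations

* The flat CNV plateau makes long-duration peak latencies degenerate (see
  above); a rounded or decaying plateau would change this but has no
  quantitative basis to be calibrated against.
* The between-within df approximation is anti-conservative in principle
  for small group counts; its empirical size is checked only for the
  designs simulated here.
* The free-lapse fit bounds λ at 0.06 and can sit on that bound for noisy
  cells; the bound is reported, not hidden.
* Single-trial feature extraction exists behind a flag for exploration but
  is far noisier than the condition-average mode and is not covered by the
  recovery guarantees.
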