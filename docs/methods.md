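# Methods

This note documents the model, the numerical conventions, and the
design choices made where the construction was genuinely open, along
with what the synthetic-data generator does and does not emulate.

## The accumulator and its discretization

The decision variable follows the leaky stochastic accumulator

    dx = (I − k·x) dt + c·ξ_β √dt,      x(0) = x0 = 0,

integrated per sample as `x[t+1] = x[t] + (I − k x[t])·dt +
c·√dt·ξ[t]` with `dt = 0.001` time units per sample (1000 samples per
unit; one unit is displayed as one second). In the noiseless limit the
trajectory is `(I/k)(1 − e^{−kt})` and the first passage of a level θ
< I/k occurs at `t* = −(1/k)·ln(1 − kθ/I)`; the simulation matches
both to O(dt), which the tests assert.

Two conventions required a decision because autocorrelated noise has
no canonical stochastic-calculus scaling:

* **√dt on the noise term.** With `c·ξ·dt` the white-noise (β = 0)
  limit of the model is essentially deterministic (the noise
  contributes ~3×10⁻³ of the threshold scale), so *every* β produces a
  strongly negative wait–W correlation and the white-noise control
  condition loses its meaning. The `√dt` scaling is the standard
  accumulator convention, reduces exactly to the classic white-noise
  model at β = 0, and produces the intended regime at β = 1.4:
  right-skewed waiting times, model W near −0.17 time units, and a
  negative wait–W correlation that vanishes for white noise.
* **Threshold crossing is closed** (`x ≥ θ`, a trajectory starting at
  θ crosses at index 0), and censored trials (no crossing within
  `max_samples = 60 000`, i.e. 60 time units) are flagged, excluded
  from crossing-time distributions and epoch averages, and never raise.

The advance-warning threshold defaults to θ_w = 0.9 θ (the value is
only ever described as "slightly lower" than θ, so it is configurable).
W is the delay from the **last** upward crossing of θ_w before the
main crossing (the final approach) to the main crossing, a value ≤ 0.
The first-ever crossing is available behind `w_rule="first"`; it makes
W strongly dependent on early spurious touches of θ_w and was rejected
as the default because the lower threshold is meant to be an imminence
signal, not a first-touch detector.

Event-locked epochs span 5000 samples before to 500 after the
crossing, for both the stochastic input and the output; samples before
trial start (or past its end) are NaN and excluded pointwise from
averages, so short-wait averages are noisier at their early tail —
exactly the missing-data structure the analyses must tolerate.

## Pink-noise generation

White Gaussian noise is transformed with an FFT, the positive-frequency
amplitudes are multiplied by `(f/f0)^(−β/2)` (power slope −β), the DC
bin is zeroed (the series is mean-zero by construction), and the
transform is inverted; phases are untouched, so β = 0 is the identity.
Admissible range 0 ≤ β < 3.

The multiplier's intercept — equivalently, whether and how the shaped
series is re-normalized — is a free choice with real consequences,
because it decides how the *effective noise amplitude* varies with β
at fixed `c`:

* **Unit mode** re-standardizes to zero mean and unit variance. This
  is the default for the standalone noise API and for spectral test
  signals: it keeps `c` meaningful across β and satisfies the strict
  standardization invariants (|mean| < 10⁻¹⁰, |var − 1| < 10⁻⁶).
* **Anchored mode** (the accumulator's input) keeps the variance the
  multiplier implies, with the reference frequency f0 = 0.1 Hz. β = 0
  then coincides with unit-variance white noise — the classic model —
  and raising β tilts power from fast into slow fluctuations while the
  slow-fluctuation amplitude stays anchored, so total variance falls
  with β. Unit-variance noise at all β was rejected for the
  accumulator input because it makes the high-β input so strong and
  jittery that the inter-threshold delay collapses to a few
  milliseconds and the output-locked tercile ordering inverts —
  i.e. the model loses the phenomena it exists to produce. f0 was
  fixed once at 0.1 Hz after a coarse scan (1/60 to 1 Hz) for the
  configuration that best produces the β = 1.4 reference regime
  described above.

The comparison input family is white noise through a causal first-order
Butterworth low-pass (default cutoff 1 Hz): unit gain in the passband
and a single-pole f⁻² power roll-off, standardized like the rest.

## Spectral-exponent estimation

β is estimated as the sign-reversed OLS slope of `log10(PSD)` versus
`log10(f)` fit to the *fractal* component of the spectrum, obtained by
IRASA: for h ∈ {1.1, 1.15, …, 1.9} the series is resampled by h and
1/h (rational-factor polyphase resampling, anti-aliasing implicit),
Welch PSDs (Hann, 4096-sample segments, 50 % overlap) of the two copies
are combined bin-wise geometrically — a pure power law is invariant
under this pairing — and the median over the h-set is the fractal
component; the residual holds oscillatory peaks. The default fit band
0.1–25 Hz avoids DC and Nyquist-adjacent bins. On 2^17-sample shaped
series the estimator recovers β = 1.4 with a mean error below 0.01 and
SD ≈ 0.013 across realizations; a pure 5 Hz tone moves the estimate by
less than 0.1. Estimates are scale-invariant. Concatenated short
epochs (as produced by the synthetic cohort) are accepted; the
concatenation seams add a small broadband component, which is why the
cohort-level tolerance is ±0.3 rather than the continuous-series ±0.1.

## Simultaneous fitting

A fit target holds an event-locked waveform (negative-going, on a time
grid relative to the event) and a normalized waiting-time histogram
(default 40 equal-width bins up to the 99th percentile). At each
objective evaluation the model is simulated (fresh batch, fixed
per-evaluation seed — common random numbers make the objective
deterministic in the parameters), the chosen average (input- or
output-locked) is sign-reversed and interpolated onto the target grid
over the fit window (default −3 to 0 s), and the amplitude scale is
profiled out in closed form (the residual is linear in it) rather than
searched — one fewer simplex dimension with an identical optimum. Each
residual block (waveform, density) is divided by the RMS of its target
block so neither dominates; the objective is the mean of the squared
concatenated residuals. Amplitude scaling applies to the waveform
only: a normalized density has no meaningful scale. Simulations that
produce fewer than 30 crossings return a large finite penalty (10⁶).

The search is Nelder–Mead in a logit-transformed space (bounds: β ∈
[0, 2.9], I ∈ [0.02, 0.3], k ∈ [0.1, 2], θ ∈ [0.03, 0.4]), started
from the best points of a coarse grid pre-search (ties broken toward
smaller β), with restarts; the best point is re-evaluated at a larger
trial count for the reported MSE. Recovery at the packaged sizes
(6000-trial target, 1000 trials per evaluation, 20 000-sample trials):
a β-only fit returns 1.44 against a generating value of 1.4. The same
machinery with the low-pass-filtered white-noise input family fits a
pink-noise-generated target over an order of magnitude worse — the
model comparison the input families are meant to support.

## Statistics

* **Tercile split:** nearest-rank 33rd/67th percentiles; boundary ties
  join the inner (short/long) groups; an all-tied split is rejected as
  degenerate.
* **Pointwise tests:** across subjects (paired), a vectorized Wilcoxon
  signed-rank statistic S = Σ sign·rank with exact sign-flip variance
  Σ rank²; across trials (independent), a rank-sum z, NaN-aware per
  time point.
* **Cluster correction:** clusters are contiguous runs with
  uncorrected two-tailed p < 0.05, positive and negative runs
  separately; the cluster statistic is the sum of z; the null is the
  maximum absolute cluster statistic over within-unit sign flips
  (default 1000), with add-one corrected p-values. Under a smooth
  paired null (14 units) the measured family-wise error over 200
  repetitions is 0.035 — calibrated at the nominal 0.05.
* **Correlations:** pooled Pearson r, p and OLS slope; per-subject r
  (subjects with < 3 trials or zero variance are excluded and
  flagged); Wilcoxon signed-rank across the per-subject r; an exact
  one-sided binomial tail P(X ≥ k | n, ½) for the sign count
  (13 of 14 → 15/16384 ≈ 0.0009).
* **Sign conventions:** scalp-convention potentials are negative-going;
  every "higher/lower amplitude" statement in code and tests is made
  on the sign-reversed (positive-going) model scale to avoid
  double-negation errors.

## Exponent sweeps for the two predictions

`lsaccum.predictions` measures where each prediction emerges as β
grows, at the reference parameters with 2000 crossing trials per grid
point: Prediction 1 on the grid 0.1–1.4 (step 0.1) via the early-window
(−1500 to −500 samples) tercile differences, Prediction 2 on 0.6–1.8
(step 0.2) via the Pearson correlation between crossing time and W
delay, reporting the smallest exponent from which the defining
condition holds for all larger grid values.

A caveat that matters when interpreting these onsets: both effects
grow *continuously* with β, with weak precursors at small exponents
(tercile differences of a few 10⁻³ model units; correlations of
r ≈ −0.05 around β ≈ 0.8). An onset defined by statistical
significance therefore moves down as the trial count grows — at 2000
trials the correlation criterion already detects r ≈ −0.05 — and an
onset defined by sign stability detects the tercile reversal from the
bottom of the grid. The qualitative transitions (the reversal being
well-established above β ≈ 0.5, the correlation becoming substantial,
|r| ≳ 0.1, only above β ≈ 1.2) sit higher than these high-power
mechanical onsets. The sweeps report the mechanical onsets; the test
suite asserts the stability of the reversal above 0.5 and the presence
of the correlation at and above 1.4 alongside its absence at β = 0.

## Synthetic cohort

Defaults: 14 subjects × 60 trials, per-subject exponent drawn from
N(1.4, 0.52) clipped to [0.2, 2.8] (SD chosen so a 14-subject group
has SEM ≈ 0.14), epochs −3.5 to +1.0 s at 250 Hz (1126 samples).

* **Waiting-time calibration:** the trajectory does not depend on θ, so
  a subject's calibration simulates 96 trajectories once and bisects θ
  on their running maxima until the median crossing time hits the
  target (7.1 s). Subject medians then scatter around the target with
  the sampling variability of a 60-trial median from a heavy-tailed
  distribution.
* **W calibration:** θ_w/θ is bisected so the subject's *mean reported
  W* — model delay plus Gaussian report noise (SD 0.15 s, a declared
  stand-in for unmodelled report variability, sized to put the pooled
  correlation in a weak-effect regime), clamped to ≤ 0 and quantized
  to the 50 ms clock tick — hits the target (−0.142 s).
* **Epochs:** the input-locked epoch of each trial is sign-flipped to
  the negative-going convention, scaled to microvolt-like units
  (group-average potential ≈ −7 µV at the crossing), zero-phase FIR
  low-pass filtered and decimated 1000 → 250 Hz, NaN-padded where the
  trial does not cover the window, and given additive white sensor
  noise (0.45 µV). The sensor noise is deliberately small compared to
  real single-trial EEG so that the input's spectral exponent remains
  estimable from a subject's short concatenated epochs.
* **Task labels:** half the trials are labelled "interruptus" purely as
  a grouping column; the generator does not model the interruption
  manipulation.

Round-trip storage is a directory with one array file (`epochs.npz`),
a delimited behavior table (`behavior.tsv`, read back with round-trip
float parsing) and versioned JSON metadata; an incompatible major
schema version is rejected, a newer minor version warned about.

What passing pipeline tests show — and what they do not: the generator
reproduces the *statistical structure* the analyses assume (skewed
waits, calibrated W, 1/f epochs with the tercile and correlation
signatures, their disappearance under white noise). It contains no
volume conduction, no ocular or movement artifacts, no oscillatory
(alpha/beta) components, no inter-electrode structure, and report
noise is an ad-hoc Gaussian; success on these cohorts demonstrates the
pipeline's correctness, not its robustness to real-EEG nuisance
structure.

## Problem sizes

The packaged defaults keep every analysis single-core friendly: 2000
trials per sweep point, 96 calibration trajectories and 60 trials per
synthetic subject, 1000 simulated trials per objective evaluation
(2000 for the final re-evaluation in tests), 1000 permutations per
cluster test, and 20 realizations of 2^17 samples for the spectral
consistency check. Each of these is a configuration parameter, not a
hard-coded constant.

## Known limitations

* The dt/√dt convention and the shaping intercept are irreducible
  modelling choices for autocorrelated noise; both are documented
  above and configurable, and the sweep onsets in particular are
  sensitive to them.
* Anchored shaping makes total noise variance depend on the series
  length through the lowest resolved frequency; trials of very
  different lengths are not directly comparable at fixed (β, c).
* Nelder–Mead on a stochastic objective inherits the realization bias
  of common random numbers; at small per-evaluation trial counts the
  β landscape flattens on the high side, so recovery tolerances below
  ±0.2 would require larger simulations.
* Group-level inference uses the normal approximation of the
  signed-rank statistic pointwise (n = 14 units); the cluster-level
  inference is exact by permutation, which is what the calibration
  test checks.
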