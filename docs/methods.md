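# Methods

## The sensing problem

Nickel-nanostrand (NiNs) / nickel-coated-carbon-fiber (NCCF) silicone
composites are *inverse* piezoresistive: at rest their resistance is very
high (hundreds of MΩ), and beyond a critical strain it falls monotonically —
by many orders of magnitude — with further stretch. Taped across the lower
back, such a gauge deforms with spinal flexion, so its resistance encodes
sitting posture. `piezopose` models this sensor, simulates the acquisition
electronics, and classifies the resulting signal into three postures:
normal sitting, slight hunchback, severe hunchback.

## Sensor model

The strain–resistance response of a conductive composition is modeled as a
scaled log-normal shape:

    R(ε) = d / (√(2π)·a·c·ε) · exp(−(ln(ε/c))² / (2a²))

with shape parameter `a > 0`, strain scale `c > 0` (strain fraction) and
amplitude `d > 0` (Ω·strain). The curve rises to a single maximum at the
**critical strain** `ε_c = c·e^(−a²)` and decreases strictly beyond it; the
decreasing branch is the usable working range. The **average gauge factor**
over a window `[ε_lo, ε_hi]` is defined as `|R(ε_hi) − R(ε_lo)| /
(R(ε_lo)·(ε_hi − ε_lo))`, with the default window `[ε_c, ε_c + 0.10]` (a
10% working-strain range). The normalization by the resistance at the
window start is a design choice; no universal convention exists for
non-monotonic gauges.

**Fitting.** Measured resistances span ~7 decades, so `fit_piezo_params`
minimizes squared residuals in log10(resistance), parameterized as
(ln a, ln c, ln d) to enforce positivity, via `scipy.optimize.least_squares`
(Levenberg–Marquardt). The warm start is closed-form-consistent: `c` at the
observed peak strain, `a = 0.5`, `d` scaled to the peak height. R² is
reported in the same log10 space as the objective. A constant-resistance
sweep carries no shape information and is rejected outright; non-convergence
raises an error that carries the best-so-far parameters.

**Resting state.** The log-normal form tends to 0 as ε → 0, while the
physical device rests at very high resistance. The simulator therefore
evaluates the model only for ε ≥ 1e-4 and clamps reported resistance at
220 MΩ (a typical bench-multimeter ceiling). Drift, hysteresis and
relaxation are out of scope.

**DOE screening.** The packaged block-DOE table crosses NiNs (3–11%) with
NCCF (0.5–2.0%); cells are conductive (with gauge factor and critical
strain), not conductive (NC), or failed mechanically (MF).
`select_composition` filters to conductive cells and selects
lexicographically: maximum gauge factor, then minimum critical strain, then
lowest total filler (manufacturability and stiffness both favor less
filler). The exact weighting of the two objectives is genuinely open; the
lexicographic order is documented and the packaged table's winner
(11% NiNs / 2.0% NCCF) is insensitive to it, since that cell wins both
objectives. `fit_response_surface` fits a full quadratic (six terms,
including the interaction) in the two volume fractions to each of (a, c, d)
by OLS (statsmodels), reporting per-coefficient p-values; it requires at
least six design points at full design rank. Note that raw quadratic
coefficients on a narrow DOE grid are ill-conditioned — predictions at
design points are the stable quantity, and that is what the tests check
under noise.

## Acquisition simulator

The simulator replaces the wearable hardware (microcontroller + Bluetooth)
and defines the conditions for all synthetic experiments:

- **Posture → strain.** normal 0.01, slight hunchback 0.05, severe
  hunchback 0.09 (strain fraction), inside the 0–10% design range and
  strictly increasing with severity. Transitions between held postures are
  1 s linear ramps (the hardware protocol does not specify transitions; 1 s
  is a realistic voluntary postural change).
- **Body jitter** is an Ornstein–Uhlenbeck process on strain (exact
  discretization), default SD 0.002 strain with 1 s correlation time —
  gentle postural sway. Its statistics are a modeling choice; only its
  existence is physically given.
- **Sensor** defaults to parameters representative of the selected
  composition: `a = 1.5`, `c = 0.006·e^(a²)` (so ε_c = 0.006),
  `d = 1.1e4`, placing working resistance near 1 MΩ mid-range.
- **Divider + ADC.** 5 V supply, 1 MΩ fixed resistor on the *measured* leg
  (so lower sensor resistance ⇒ higher reading), v = Vs·Rf/(Rf + R), ideal
  10-bit conversion (counts 0–1023), 50 Hz sampling, white measurement
  noise of 2 counts SD, clipped to range.
- **Firmware smoothing**: a trailing (causal) rolling mean over the
  previous 2 s (100 samples; warm-up averages the samples seen so far),
  rounded back to integer counts. This is distinct from the offline
  centered filter below.
- **Inter-subject variation**: each simulated session multiplies each
  posture's nominal strain by an independent log-normal factor with
  relative SD 0.10 — different bodies produce different strains in the same
  posture. Per-session seeds are spawned from one dataset seed
  (`numpy.random.SeedSequence`), so datasets are exactly reproducible and,
  with both noise SDs at zero, the chain is fully deterministic.

The standard session holds each of the three postures for 10 s
(1500 samples); the standard dataset is 350 sessions → 5250 feature
vectors. What the generator does *not* emulate: sensor drift and
hysteresis, relaxation dynamics, electrode/cable artifacts, posture-specific
movement signatures, or per-subject session correlation (sessions are
exchangeable; subject identity is not modeled). Passing tests on this data
therefore demonstrate the correctness and internal consistency of the
pipeline under the stated noise model, not field performance on human
recordings.

## Signal processing and features

Offline preprocessing applies a centered moving average of N = 2k+1
samples; at the boundaries the window truncates and the divisor shrinks, so
output length equals input length. N is configurable with default 5 — a
light smoother; the upstream firmware average has already removed most
high-frequency noise. The filtered trace is cut into consecutive
non-overlapping 100-sample (2 s) windows — an incomplete tail is dropped —
and each window summarized by mean, population standard deviation, maximum
and minimum of the counts, labeled by the window's majority posture (ties
toward the earlier posture; at default settings windows never straddle
postures since 500-sample blocks are multiples of the window).

**Normalization.** Two min–max conventions are implemented:

- *per-vector*: each vector's four elements rescaled by that vector's own
  min and max. This pins the largest element (the window max) to 1 and the
  smallest (almost always the std) to 0, leaving only two ratios that are
  nearly class-independent. Measured on the default dataset the end-to-end
  pipeline then plateaus near 72% accuracy regardless of dataset size,
  epochs, or hidden width — the convention discards most of the class
  information.
- *dataset* (pipeline default): each feature column rescaled by its min and
  max over the whole table, preserving between-feature structure. ADC gain
  and offset still cancel.

Both conventions are exposed and tested; the pipeline defaults to the
dataset-wide convention because it is the one under which the task is
solvable at the accuracy this system is designed for.

## Classifier

A three-layer perceptron, 4 inputs → k tanh hidden units → 3 logistic
outputs. The width heuristic `k = round(√(n_in + n_out)) + slack`,
slack ∈ [1, 10], seeds an empirical width sweep; the default network uses
k = 4 (slack 1). Weights initialize uniform [−0.5, 0.5] from a seeded
generator. The loss is the mean squared error between logistic outputs and
one-hot targets — the quantity the classic feed-forward toolboxes report —
deliberately not softmax/cross-entropy. Training is full batch.

Five trainers, written from scratch (backprop gradients are verified
against central finite differences to 1e-6 relative in the tests):

- **gd** — steepest descent, fixed learning rate.
- **gdm** — heavy-ball momentum (default 0.9).
- **gda** — adaptive rate: grow ×1.05 on improvement; on *any* loss
  increase the step is rejected (weights reverted) and the rate shrinks
  ×0.7. The classic toolbox variant accepts increases up to 4%; rejecting
  all increases keeps accepted-step loss monotone (an invariant the test
  suite enforces) and avoids an accept/reject limbo at a fixed rate.
- **rp** — Rprop: per-weight step sizes Δ (init 0.07, ×1.2 on consistent
  gradient sign, ×0.5 on flip, bounded [1e-6, 50]), sign-based updates,
  flipped-sign gradients forgotten (the "Rprop−" rule), plus a global
  backtracking rejection: if a step increases the loss it is reverted and
  all Δ halve. Plain Rprop has no rejection; the backtracking variant makes
  accepted steps monotone at negligible cost on these problems.
- **lm** — Levenberg–Marquardt on the per-sample per-output residuals
  r = y − t: solve (JᵀJ + μI)δ = Jᵀr, accept on improvement (μ ×0.1),
  otherwise raise μ ×10 and retry within the epoch; stop if μ exceeds 1e10.
  With μ → ∞ the step direction collapses to the gradient (verified
  numerically); with μ = 0 it equals the Gauss–Newton step of an
  independent QR least-squares solve (also tested).

Learning-rate defaults: `TrainerConfig` defaults to 0.001, which for lm is
the initial damping μ₀ (the natural reading of a "learning rate" quoted for
a Levenberg–Marquardt network). For the cross-algorithm benchmark,
`toolbox_trainer_configs()` gives the gradient methods their classic 0.01
default: at 0.001, plain descent cannot reach any common error goal in a
sane epoch budget on the default dataset, which would make epochs-to-goal
comparisons degenerate (everything capping out). The benchmark protocol is
a shared goal of MSE 0.02 with a 20 000-epoch cap; on the default dataset
this yields the epoch ordering lm < rp < gda < gdm < gd, the classic speed
ranking of these batch trainers.

Stopping: error goal, epoch cap, μ overflow, or optional validation-based
early stopping (fraction 0.15, patience 6) — the latter is disabled
(fraction 0) in the pipeline and benchmark so that epoch counts reflect the
optimization itself. Runs are bit-reproducible given (seed, config, data).
Prediction is argmax of the output scores, exact ties to the lowest class
index.

## Evaluation

Random 80/20 train/test split (non-stratified by default, since nothing in
the protocol implies stratification; a stratified mode exists because class
counts in a random split are unequal). The confusion matrix has true
postures in rows and predictions in columns, in the order (normal, slight,
severe). Accuracy is trace over total; sensitivity is row-wise TP/(TP+FN);
precision column-wise TP/(TP+FP); a class absent from the test set reports
NaN, not zero. Accuracy equals the count-weighted mean of sensitivities
(property-tested). Percentages print to two decimals.

## Problem sizes and numerical choices

The default study scale — 350 sessions, 5250 vectors, 4200/1050 split — is
used by the end-to-end tests and runs in seconds per pipeline invocation;
smaller cohorts (20–60 sessions) back the unit tests and examples. The
sensor fitter uses xtol/ftol/gtol 1e-15 so noise-free round-trips recover
parameters to 1e-6 relative. Degenerate inputs are first-class: constant
sweeps, all-equal feature vectors (normalized to zeros with a warning),
traces shorter than one window (empty result with a warning), single-class
training data (error), all-zero confusion matrices (error).

## Known limitations

- The synthetic cohort has no subject identity, so subject-blocked
  cross-validation cannot be expressed; accuracy is per-vector, not
  per-person.
- The per-vector normalization convention is retained for completeness but
  is not fit for purpose (see above).
- The log-normal model cannot represent the high resting resistance at
  ε → 0; the clamp is a pragmatic patch, adequate because all postures sit
  well above the critical strain.
- Gauge factors larger than 1/Δε over a window are impossible under the
  R₀-normalized definition when resistance decreases; screening-table gauge
  factors are treated as data, not recomputed from the model.
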