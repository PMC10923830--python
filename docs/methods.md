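# Methods

## The estimand and the estimator

For one neuron and one task epoch, the observations are spike counts in
fixed-width bins (default 50 ms, 16 bins covering 0–800 ms after the aligning
event).  The design factors are the trial's task conditions: reward
probability (2 levels, cued by target color), movement direction (8 levels at
45° spacing, defined at target motion onset), and reward outcome
(delivered/omitted, resolved at the outcome event).  Each epoch uses only the
factors whose values are known to the subject in that epoch — reward
probability alone in the cue epoch, reward probability × direction in the
motion epoch, all three in the outcome epoch — always with every interaction.

Sums of squares are **Type II**: each term's SS is the SSE drop when the term
enters a model containing every term that does not contain it (marginality is
respected — a main effect is never adjusted for its own interactions).  This
is the standard choice for unbalanced data, where outcome counts necessarily
differ across probability conditions (reward is a Bernoulli draw at 0.25 or
0.75) and direction counts fluctuate multinomially.  On balanced designs it
reduces exactly to the classical sequential decomposition.

Implementation: full-rank sum-to-zero design-matrix blocks per term; each
model's SSE is obtained by projecting the response onto an orthonormal basis
of the model's column span (SVD with a relative rank tolerance of 1e-9).
Comparing spans rather than coefficient fits makes the decomposition exact on
rank-deficient designs.  A term whose columns add fewer dimensions than its
nominal degrees of freedom — an interaction with an empty cell — is flagged
inestimable and excluded for that neuron rather than failing the batch, since
at modest trial counts a stochastic outcome can empty a cell.  Degrees of
freedom are rank increments, so they remain correct in those edge cases.

Per-term effect sizes:

- per bin: `ω²p = (SS_T − (df_T/df_err)·SS_err) / (SS_T + ((N − df_T)/df_err)·SS_err)`
  with N = number of trials;
- whole epoch: time (the bin index) is added as a factor with all
  interactions, the term of interest is pooled with its term × time
  interaction in both numerator and denominator, and N = trials × bins.  The
  interaction pooling is what lets a purely time-varying code (identical
  marginal means, different temporal profiles) register as a positive effect.

ω²p is reported **unclipped**: its unbiasedness under the null (mean ≈ 0 for
any number of conditions) requires negative estimates to survive.  Partial η²
(`SS_T/(SS_T + SS_err)`) is computed alongside as the biased reference — its
null mean is positive and grows with the condition count, which is the reason
ω²p is the headline statistic.  When a response is exactly constant the
estimand is undefined; the implementation returns 0 with a warning
(a conservative fixed point), and constant responses are detected exactly
(zero variance) rather than through a float tolerance.

Per-neuron significance uses the parametric F test on the pooled
(term + term × time) mean square against the full-model error mean square;
the same construction with the time main effect defines the "time-varying
neuron" flag.  The default α is 0.05 and configurable.  Parametric F is
appropriate here because the test is within-neuron on Poisson-ish counts;
**across-population** comparisons never use it (below).

## Across-population inference

Per-neuron effect sizes are non-normal with population-dependent variances,
so group comparisons use:

- permutation one-way **Welch ANOVA**: population labels permuted uniformly
  (group sizes preserved), p = probability of a permuted Welch (1951) F at
  least as large as the observed one;
- permutation **Welch t** (two-tailed on |t|) for pairwise contrasts, with
  the group pair canonically ordered internally so p is exactly
  swap-invariant;
- **mean-centered bootstrap t** for "is the mean effect size (or paired
  difference) zero": the null is simulated by resampling the mean-subtracted
  sample with replacement, two-tailed on |t|.

Monte-Carlo p-values use the add-one rule p = (1 + #extreme)/(1 + R), which
avoids p = 0 and is the standard conservative estimate; ties count as
extreme.  Default R = 10,000 resamples.  An `exact=True` mode enumerates all
label permutations (feasible at small n), where p = #extreme/total with the
observed labeling included; the Monte-Carlo p estimates exactly that
quantity.  Degenerate bootstrap resamples (all values identical) get |t| = ∞
when their mean is nonzero, 0 otherwise — again conservative.

Calibration at 1,000 resamples and 2,000 null replicates holds the 0.05 level
within the exact binomial 99.9% interval for all three tests, including a
4-group Welch ANOVA with standard deviations spanning 1–8; this is recomputed
by `scripts/acceptance.py`.  No multiple-comparison correction is applied
across contrasts — the reported pairwise tests are uncorrected by design.

## What the synthetic generator emulates — and what it does not

A session is a trial table (reward level balanced to within one trial via
shuffled alternating pairs, i.i.d. assignment available by flag; directions
uniform; outcome Bernoulli at the cued probability; cue → motion → outcome
event times on one session clock with the task's delay ranges) plus Poisson
neurons and 1 kHz eye traces.

The within-epoch firing rate is
`baseline · g_reward(condition) · (1 + depth_c · cos(direction − preferred)) · 1[t ≥ latency]`,
with cosine tuning active in the motion epoch, an optional outcome gain in
the outcome epoch, and `interaction_gain` making the tuning depth differ
between reward conditions (`depth ± interaction_gain/2`) — a genuine
reward × direction interaction with zero marginal direction change.
Preferred directions are drawn from the 8 task angles so tuning curves peak
at a sampled direction.  Spikes are per-1-ms Poisson counts (the exact
process at the task's 1 ms timestamp resolution); a `simulate_counts` /
`expected_counts` fast path draws per-bin counts directly, which is
distributionally identical and is what the large replicate studies use.
Defaults: 160 trials (the study scale is "at least 55, median ≈ 141"
successful trials per neuron; 160 gives 80 per reward level and ~20 per
direction), probabilities 0.25/0.75, 800 ms epochs, 50 ms bins, 20 Hz
baseline.

Because counts are Poisson, every term's population effect size is available
in closed form: σ²_effect is the equal-weight variance of the term's
cell-mean contrasts of expected counts, σ²_error the mean expected count,
pooled over bins by summation — the same weighting the whole-epoch estimator
applies.  `population_omega` computes this exactly for the generator's
piecewise-constant rates; a Monte-Carlo variant cross-checks it.
`reward_gain_for_omega` inverts the map by bracketed root finding, which is
how the recovery and decoder studies plant effect sizes of 0–0.8.

Eye traces follow the task kinematics: pursuit ramps to 20°/s with a 50 ms
time constant after a ~100 ms latency (smooth stop at motion end), saccade
trials jump 10° after a ~200 ms latency; catch-up saccades (1–3°),
outcome-dependent return saccades (3–8°) and blinks are injected as
raised-cosine displacement profiles and flagged-missing intervals, all
recorded as ground-truth annotations.  Return saccades are placed outside
blink intervals — an event hidden by a blink is unobservable and would be an
unfair detection target.  Position noise is 0.005° SD white noise, small
enough that 5 ms Gaussian smoothing keeps derivative noise far below the
detection thresholds, as for a good 1 kHz tracker.

Not emulated: oculomotor plant dynamics (no main-sequence scatter, no
pursuit gain variability), non-Poisson spiking (refractoriness, bursting),
complex spikes, camera blink artifacts (blinks are clean missing-sample
gaps), and any correlation between neurons.  Passing tests therefore
demonstrate correctness of the estimators and detectors under the declared
statistical structure, not robustness to every property of recorded data —
most importantly, real spike counts are often over-dispersed relative to
Poisson, which changes effect-size magnitudes but not the estimator algebra.

## Behavioral preprocessing

Velocity and acceleration come from central differences of the 5 ms-SD
Gaussian-smoothed position; blink gaps are linearly interpolated before
smoothing and a blink mask padded by the kernel support marks invalid
samples.  A sample is saccadic when radial acceleration exceeds 1000°/s² or
radial speed crosses 15°/s (fixation) / 50°/s (pursuit target motion).
Crossing runs merged across ≤20 ms gaps, runs shorter than 10 ms dropped,
and boundaries extended outward to where speed falls below 20°/s (fixation)
or 30°/s (pursuit) so the excision interval covers the whole movement; the
merge gap, minimum duration and boundary thresholds are configurable — the
original procedure was verified by visual inspection, which a pipeline must
replace with explicit rules.  Saccade-excised averaging projects velocity on
the trial's target direction, averages over trials treating excised/blink
samples as missing, and smooths with a 20 ms-SD Gaussian using normalized
(mass-preserving) convolution over the missing-data mask.

The outcome-epoch control first drops trials with a blink onset in the first
500 ms after the outcome, then — within each direction stratum, to avoid
trading direction balance for outcome balance — randomly discards trials
from whichever outcome condition has more early-saccade trials until the
counts match exactly.  Stratification by direction is this package's choice;
an unstratified variant would equate marginal counts only.

## Decoder

The nearest-PSTH classifier assigns each held-out trial the label of the
closest (L2 over the epoch) class-template PSTH computed from training
trials only.  Single-trial rates use the same 20 ms Gaussian kernel and
edge-trimmed window as the displayed PSTHs (the trim, 100 ms = 5 SD,
guarantees no filter edge artifacts inside the window).  Folds are
stratified by class — with 10 folds and few trials per class an unstratified
split can lose a class from a training set — and ties break toward the first
class in sorted label order.  Accuracy is deliberately *not* invariant to a
common rate rescaling: L2 distances scale with rate, and that is expected
behavior, not a bug.  Whole-epoch ω²p and decoding accuracy are strongly
rank-correlated across neurons spanning effect sizes 0–0.8, which is the
point of carrying both.

## Numerical and design choices

- Bins are half-open `[a, b)`; a spike exactly on an edge belongs to the
  later bin.  Trials missing the aligning event are dropped with a warning.
- PSTH smoothing is direct FIR convolution with a Gaussian truncated at
  ±5 SD, computed on a window extended by the trim and cropped afterwards.
- Waveform width is trough-to-*following*-peak after zero-phase band-pass
  filtering (250–6000 Hz, 2nd-order Butterworth, forward-backward so no
  filter delay biases the width); a waveform whose trough is its last sample
  is rejected rather than silently using a pre-trough peak.
- Preferred direction is the sampled angle nearest the rate-weighted vector
  average; equidistant ties break to the smaller angle; a zero resultant
  (uniform tuning) raises rather than guessing.
- The effect-size regression on log firing rate and log waveform width
  offers two interaction terms: `log(rate)·log(width)` (default) and a
  literal `log(rate)²` variant, because the natural cross-term and the
  squared-rate term are both defensible readings of the published form of
  this analysis; neither is asserted as canonical.
- Pipeline runs are reproducible: every stochastic step derives from the
  config seed, outputs carry a config hash (I/O paths excluded so identical
  analyses hash identically), and rerunning a config reproduces numeric
  tables byte for byte.

## Problem sizes in the shipped studies

The replicate studies in `scripts/acceptance.py` use 1,000 simulated neurons
per condition count for the bias study, 200 random designs for the Type II
oracle, 500 replicates per planted effect size for recovery, 2,000 replicates
at 1,000 resamples for calibration, 1,000 annotated trials plus 400 clean
traces for saccade detection, 200 neurons for the decoder and bin-width
studies, and 1,000 null plus 10 × 500 alternative neurons for interaction
specificity.  These sizes give Monte-Carlo standard errors comfortably inside
every stated tolerance while keeping a full run to about a minute on one CPU.

## Known limitations

- Whole-epoch ω²p treats bins as exchangeable observations; serial
  correlation within trials (absent in Poisson simulation, present in real
  data) would inflate the nominal error degrees of freedom.
- The Type II convention, while standard for unbalanced factorial data,
  penalizes terms that are collinear with their siblings; with heavily
  unbalanced cells the main-effect SS can be small even when cell means
  differ.
- Permutation Welch tests are asymptotically, not exactly, valid when group
  variances differ (labels are not exchangeable under heteroscedasticity);
  the studentized statistic keeps the level accurate at the tested sizes
  (n = 30 per group), but very small groups with extreme variance ratios are
  untested territory.
- The blink "detector" reads the generator's missing-sample flag; detecting
  blinks from raw camera artifacts is out of scope.
- The Dryad-deposit loader for the original recordings is not implemented;
  the on-disk formats are this package's own CSV/JSON layout.
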