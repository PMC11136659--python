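# Methods

This note documents the models, statistical procedures and design choices in
`wmcrys`, and what the synthetic-data validation does and does not show.

## Task and data model

Trial time 0 is first-odour onset.  The default timeline is 5 s baseline,
1 s first odour, 5 s delay, 1 s second odour, 3 s choice window (15 s per
trial), imaged at 10 Hz (configurable 6.45–17 Hz).  All windows are
half-open `[start, end)`; frames belong to a bin if their *start* time falls
inside it.  The analysis unit is nonnegative deconvolved event amplitude;
the pipeline deliberately starts downstream of motion correction,
segmentation and deconvolution.

**Epoch boundaries.** Early delay defaults to the first 2 s of the delay
and late delay to the last 2 s (delay seconds 4–5, the behaviourally
critical interval), leaving the middle second unassigned; both spans are
configurable.  There is no canonical published boundary for these analysis
epochs — this is the package's declared choice.

**Binning.** Activity is aggregated into 500 ms bins by **sum** (event
mass), not mean: deconvolved output is event-like and summing preserves
total event mass.  A trailing partial bin is dropped so every trial shares
one binned shape; total mass is conserved exactly when the trial extent is a
multiple of the bin width.

**Response maps.** The z-scored trial-averaged trace (baseline mean
subtracted, divided by baseline s.d.) is a visualization aid only; all
statistics run on raw event amplitudes.  A zero baseline s.d. yields a
flagged all-zero map rather than an error, since silent neurons are expected
under synthetic nulls.

## Synthetic cohort generator

The generator defines the study conditions for validation; its defaults are
fixed once and the tests run under them.

**Event model.** Per frame, activity = `Gamma(Poisson(λ), 1)` — Poisson
event counts with exponential(mean 1) amplitudes, i.e. compound-Poisson
event mass.  Rates are parameterized per 500 ms bin: `noise_rate = 0.2`
everywhere, and inside a selective neuron's informative epoch
`effect_rate_hi = 3.0` on preferred trials vs `effect_rate_lo = 1.0` on
non-preferred ones (a 3:1 effect; per-neuron, per-bin discriminability
d′ ≈ 1).  A pure Poisson model was rejected so that continuous-valued
statistics (rank tests, standardization) are exercised.

**Planted tuning.** Each epoch has an exact quota of
`floor(frac_selective × n_neurons)` selective neurons (the fractional
remainder is dropped).  Defaults (0.18 first odour, 0.11 early delay, 0.07
late delay, 0.10 second odour, 0.28 choice) follow typical expert-stage
prevalences in premotor populations.  Quota slots reuse an
already-selective neuron with probability `mixed_prob = 0.6` (mixed
selectivity, at most three epochs per neuron); a neuron's first-odour
preference is shared across its odour epochs.  A configurable fraction of
*pair cells* is planted with matched rewarded-pair preferences (A with C, B
with D).  Choice tuning is planted on lick/no-lick labels independently of
odour tuning, so odour and choice decoders are separable in ground truth.

**Depth gradient.** The probability that a late-delay slot goes to a neuron
increases logistically with depth.  Draws use systematic
probability-proportional-to-size sampling over depth-sorted cumulative
weights: marginal inclusion probabilities are identical to independent
weighted draws, but per-depth-stratum counts are near-deterministic, so the
realized gradient tracks its expectation closely (sequential weighted draws
realize visibly non-monotone gradients at a few hundred neurons).

**Drift and crystallization.** Across each day transition before the
crystallization day `C`, every selective neuron keeps its whole tuning
profile with probability `retention` (default 0.2); dropped quota slots are
refilled from currently untuned neurons with fresh preferences.  From day
`C` (default 6) onward tuning is frozen.  The day-to-day overlap of
selective sets therefore equals `retention` in expectation plus a small
chance-redraw term (`≈ (1−ρ)·k/n` for quota k of n neurons), which the
tests account for.

**Errors and behaviour.** Trial types are uniform random; the response is
correct except with probability `error_rate` (default 0.06, expert-level
performance ≈ 94 %).  On error trials, the late-delay effect is multiplied
by `1 − error_degrade` (default 1.0: late-delay coding fully collapses on
errors while odour and choice coding are untouched).  Sessions are
truncated by the motivation abort rule (> 3 misses in the last 10 trials);
`apply_abort=False` disables it for conditions that need many error trials,
since a high error rate would otherwise truncate sessions before enough
errors accumulate.

**Geometry and detection.** Centroids are placed with a 12 μm minimum
lateral spacing (cell bodies do not overlap), depths uniform over
30–450 μm; each day every neuron is detected with probability
`1 − detection_dropout` and its centroid is re-measured with 0.5 μm jitter.

**What the generator does not emulate.** Calcium indicator dynamics and
deconvolution artefacts; trial-wise response reliability as a separate knob
(planted neurons respond on every preferred trial in expectation); noise
correlations between neurons; slow within-session drift; behavioural lick
timing.  Passing tests therefore demonstrate the *statistical machinery* is
correct and calibrated, not that real recordings satisfy its assumptions.

## Neuron-level statistics

**Activity fields.** One-sided permutation test of epoch activation: the
observed across-trial mean epoch activity is ranked against values obtained
after circularly shifting the neuron's concatenated session trace (trials
back-to-back), one independent uniform offset per neuron per shuffle —
whole-trace shifts preserve autocorrelation; per-trial independent shifts
were rejected as too liberal.  Because every trial contributes the same
within-trial window to the mean, a shift by any multiple of the trial
length leaves the statistic exactly unchanged; offsets are therefore drawn
over the trial length's nonzero residues (no-op shifts would only add
conservative ties).  `p = (1 + #{null ≥ obs})/(n_shuffles + 1)` with floor
`1/(n_shuffles+1)`; all-zero neurons tie everywhere and get p = 1.  The
flag threshold α_field = 0.05 and sidedness are configurable; under a
stationary cohort the realized false-positive rate sits in the binomial
band around α_field.

**Selectivity.** Two-sided Wilcoxon rank-sum on per-trial epoch means,
α = 0.01; the exact null distribution when the smaller group has ≤ 10
trials and the neuron's values are tie-free, otherwise the normal
approximation with continuity and tie correction (verified against
exhaustive enumeration over all label splits for 4v4 and 5v5 groups).
Effect size is the AUC `U/(n₁n₂)`; the preferred label has the larger mean,
exact ties defaulting to the alphabetically first label with an
`ambiguous` flag.  **No multiple-testing correction across neurons**:
selective fractions are reported raw, as is standard for these prevalence
figures.  Choice selectivity uses all completed trials (not only correct
ones).

**Movement correlation.** Pearson r between each neuron and the locomotion
trace against a circular-shift null of the locomotion; significant when
|r − null mean| ≥ 2 null s.d.  All lags are computed at once by FFT
cross-correlation and the null samples random nonzero lags.  Zero-variance
traces are flagged degenerate, never significant.

**Sequence correlation.** Per-neuron Pearson r between AC- and BD-averaged
binned traces, peak-time orderings per type, and an across-neuron per-bin
correlation profile whose minimum localizes where the two types' delay
sequences diverge.

## Decoding

Per 500 ms bin: standardize features (mean/s.d. of the training split; zero
s.d. maps to 1), fit `LinearSVC(C=1)`, score the held-out split.  Splits
are stratified 90/10, `n_repeats = 32` by default, resampled if a label is
missing from a training split.  Epoch accuracy is the mean over member
bins; its s.e. is across repeats.  The decoder is linear by design (the
question is what a fixed linear read-out can extract); regularization
strength (C = 1), per-neuron standardization and per-bin training are the
package's declared defaults.

*Multiclass* uses one-vs-one voting over binary linear decoders with ties
broken by aggregate decision-function margin.  *Top-N % curves* use one
shared seed across the N grid (identical splits; a paired design), so the
N = 100 point reproduces the all-neuron run exactly.  *Depth-stratified*
decoding tiles the bottom 420 μm into seven 60 μm intervals and equalizes
neuron counts to the sparsest interval by seeded subsampling.

**Chance.** Label-shuffle chance reruns the whole protocol on permuted
labels.  Two calibration caveats are intrinsic, not bugs: (i) with
imbalanced labels the shuffled decoder converges to the majority-class
rate, not 1/n_classes; (ii) on data with real structure, a single fixed
permutation retains a spurious whole-session association shared by training
and test splits, biasing single-permutation chance off the nominal level
(the documented below-chance cross-validation effect).  Chance is therefore
summarized over several independent shuffles, and nominal-level calibration
is asserted on effect-free data with balanced labels.

**Error-trial mode.** `train_correct_test_error` trains on 90 % splits of
correct trials and tests on all error trials; its chance twin shuffles the
training labels under the identical protocol.

**Seeds.** Every routine takes one seed and fans it out through
`numpy.random.SeedSequence` children per (bin, repeat, animal, day); equal
seeds give bit-identical results.

## Cross-day stability

Neurons are matched per day pair (mutual nearest centroids within 10 μm,
greedily resolved by ascending distance, one-to-one; 3D when depth is
present).  The pairwise-intersection scope maximizes neurons per pair; an
across-all-days intersection can be supplied instead via the `matching`
argument.  Off-diagonal entries train on all day-i trials and test on all
day-j trials, per bin, matching the same-day protocol; the diagonal holds
the same-day cross-validated value so the matrix is comparable on and off
the diagonal.  Entries with fewer than 10 matched neurons are left missing.

**Block statistics.** Per animal, the mean over off-diagonal pairs within
an early and a late day block (defaults: first vs last half, e.g. 1–3 vs
5–7 for 7 days, 1–5 vs 6–10 for 10); across animals an unpaired one-sided
t-test (late > early — the hypothesis is directional).  The day-shuffle
test permutes day identities (rows and columns jointly, the same
permutation for every animal) and recomputes the block difference;
`p = (1 + #{perm ≥ obs})/(n_perm + 1)`.  Blocks need at least two days to
have off-diagonal pairs; degenerate blocks raise.

**Crystallization day.** `C* = argmax_c mean{acc(i,j): i,j ≥ c, i≠j} −
mean{acc(i,j): i,j < c, i≠j}` over candidates with at least one
off-diagonal pair per side; `None` if the best difference is below the
margin (default 0.05).  The confidence band bootstraps off-diagonal
*entries* within each side and re-estimates; bootstrapping at the trial
level would require re-running every decoder per replicate and buys little
for a change-point on an already-averaged matrix.

Comparisons of on- vs off-diagonal values at desk scale are made at the
mean level: each off-diagonal entry is a single train-all/test-all fit
whose binomial test noise (~2 points at 80–100 trials) plus real day-to-day
variation exceeds a per-entry 5-point band even under frozen tuning.

## Pipeline, formats, units

HDF5 for tensors (`/animal/<id>/day/<d>/…`, trial table as CSV text inside
the group), CSV for stage tables, YAML configs, JSON manifests; μm for
space, seconds for time, day indices 1-based.  Stages
(simulate → behaviour → selectivity → registration → decoding → stability)
are independently runnable and resumable; all randomness flows from one
master seed and deterministic stages are byte-identical across runs.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen so each
statistical band is attainable with margin: 25–500 neurons, 30–200 trials
per day, up to 10 days and 4 animals; 1000-shuffle permutation nulls;
32 decoding repeats for calibration/power checks and 8–16 where only means
across many fits matter (cross-day matrices over 20 seeds).  Power check
behind the 3:1 effect default: the per-neuron epoch-mean contrast at 40
trials/label gives z ≈ 6, so ≥ 90 % of planted neurons are flagged at
α = 0.01 with a wide margin.

## Known limitations

- The centroid matcher replaces probabilistic footprint co-registration; it
  is exact on the generator's geometry (≥ 12 μm spacing, ≤ 1 μm jitter) but
  would under-match dense or distorted real fields of view.
- Per-bin decoders ignore temporal structure within an epoch; no recurrent
  or kernelized decoders.
- The change-point estimator assumes a single block transition; gradual
  stabilization yields an estimate biased toward the steepest part of the
  ramp, visible in the bootstrap band.
- No multiple-testing correction across neurons (by design, see above);
  downstream users comparing selective fractions across conditions should
  correct at that level.
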