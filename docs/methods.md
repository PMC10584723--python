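# Methods

This note documents the models, estimators and design choices behind
`sdfaces`, and what the synthetic-observer validation does and does not
establish about real behavioural data.

## Stimulus geometry

The stimulus space is a closed wheel of `3 + 3·n_between` morphed face
images (default 46 → 141 positions) with three anchor identities at
indices 0, 47, 94. Distances are signed shortest circular paths;
increasing index (with wraparound) is positive. On the odd 141-position
wheel every distance in [−70, +70] is unique; for generalised even wheels
the tie at n/2 resolves to +n/2 by convention. Which pictorial rotation
counts as "clockwise" is arbitrary — every statistic in the package is
invariant under reflecting the wheel — so only internal consistency
matters. Each anchor owns a category of ±23 steps; 3 × 47 positions tile
the wheel exactly, which the category machinery requires (non-partitioning
wheels must be requested explicitly and cannot be used for the categorical
index).

## Trial derivation and exclusion

For the single-target design (experiment 1) the reproduction target is
always Face 2 and Face 1 is the inducer; with a postcue (experiment 2) the
cue selects the target and the other face is the inducer. The adjustment
error is the signed distance target → response; the predictor difference
is the signed distance target → inducer. Trials with response time
strictly above 15 s or |error| strictly above 60 steps are treated as
attentional lapses and excluded (boundary trials at exactly 15.0 s or ±60
steps are kept); a trial failing both criteria counts once. Analyses pool
trials across participants — per-participant (cluster) resampling is
available as an option — and group them into the design cells (ISI ×
delay, 20 cells; or postcue × delay, 6 cells). Empty or too-small cells
are carried through flagged non-estimable instead of failing the run.

## DoG bias model

The bias curve is `y = α (x − µ) N(x; µ, σ)`, i.e. a first-derivative-of-
Gaussian shape parameterised so that positive α means attraction. Its
interior extrema sit at exactly µ ± σ with magnitude |α| e^(−1/2)/√(2π)
(independent of σ; σ only sets the width). The half-amplitude is that
extremum magnitude signed by α, computed in closed form whenever one lobe
lies inside the ±70-step domain and from the domain boundary otherwise
(only reachable when σ exceeds the domain). Note one symmetry worth
stating explicitly: mirroring the wheel (negating x and y together)
preserves the curve up to µ → −µ, so attraction stays attraction; only
negating the errors alone flips the half-amplitude's sign.

### Fitting

Least squares under box constraints. α enters the model linearly, so for
any (µ, σ) the optimal α and the profiled residual sum of squares have
closed forms in per-unique-x sufficient statistics (on the wheel x is an
integer in [−70, 70], so an objective evaluation costs O(141) regardless
of trial count). The profiled surface is searched with a deterministic
zooming grid over (µ, σ) — a global 9 × 12 stage-1 grid handles the
surface's multimodality — followed by L-BFGS-B polish with the analytic
gradient from the best grid candidates (`n_starts`, default 3). Bootstrap
refits use the grid-only path (`n_starts=0`, final resolution ~0.2 steps
in µ, ~1% in σ; ~0.8 ms per refit), which leaves half-amplitude
distributions indistinguishable from polished ones at bootstrap
resolution. The fit is a pure function of its inputs; RSS ties resolve to
the smaller σ. Noiseless model data are recovered to better than 1e−6
relative error.

Default bounds: µ ∈ [−20, 20], σ ∈ [10, 70], α ∈ [−1e6, 1e6]. The σ floor
matters: an estimator-stability study on null data at the study's
per-cell trial count (~430) showed that σ < 10 basins act as single-bin
noise detectors — the null half-amplitude SD grows to ~5 morph steps
(larger than any real effect of interest) because a narrow lobe can chase
one noisy x-bin with arbitrarily large α. With the floor at 10 steps
(~7% of the wheel, narrower than any serial-dependence tuning reported
for face stimuli) the null SD drops to ~2.4 steps at that n. A small
selection-driven inflation of |half-amplitude| remains near the detection
limit (~+0.3 steps at a true amplitude of 2 with ~1,800 trials); fixing
µ = 0 (`fix_mu=0.0`) removes most of it and is recommended when a
symmetric curve is acceptable. The fitted-µ default is kept because the
centre offset is a quantity of interest (a global clockwise response
bias). Cells need at least 10 (x, y) pairs and non-degenerate x to be
estimable.

### Predictors

Four predictor variants share the fitting machinery: within-trial
(x = inducer−target difference) and three across-trial variants
(x = distance from the current target to the previous trial's Face 2,
Face 1, or response). Across-trial variants drop the first trial of each
session and any pair whose current or previous trial was excluded.
Because the previous trial may belong to a different design cell, pairs
are built over whole sessions and then assigned to the current trial's
cell.

## Bootstrap inference

CIs come from resampling trials with replacement (default 10,000
iterations; the test suite uses 1,000 through the same code path),
refitting the statistic on each resample, and reading the 2.5/97.5
percentiles; a statistic is significant when its CI excludes zero. The
DoG half-amplitude uses the percentile method. The categorical index
defaults to BCa (bias-corrected and accelerated, standard z₀/jackknife
construction, cross-checked against an independent implementation in the
tests); BCa falls back to percentile when the bias correction is
degenerate (e.g. a constant bootstrap distribution). Resample fits that
fail are excluded from the quantiles and counted; more than 20% failures
aborts the condition. Null-simulation calibration places the empirical
false-positive rate of the percentile CI at the nominal ~5% (see the
acceptance tests). No multiple-comparison correction is applied across
cells by default, matching per-cell CI logic; a Bonferroni option widens
the CIs to level 1 − 0.05/n_cells.

## Categorical classification-error index

Responses, targets and inducers are classified into the three prototype
categories. A trial is a classification error when the response leaves
the target's category. Errors are partitioned by inducer category;
within each partition the index numerator counts errors landing in the
inducer's own category. The per-partition (conditional) denominator is
used because it is the reading under which the chance level is exactly
1/3 when target, inducer and response are independent — verified by Monte
Carlo in the tests — and the printed baseline constant 33.33 is
subtracted. A grand-total denominator is available for sensitivity
analysis, as is exclusion of trials whose inducer and target share a
category (the 1/3 null holds with them included). A partition with no
errors yields an undefined ratio; the index averages the defined
partitions and flags the result. Classification accuracy is the percent
of trials whose response stays in the target's category, with a
bootstrap-resample SD as its dispersion (for a binary outcome this is the
binomial resampling distribution, which is how it is computed).

## Synthetic observer

The generator exists so every stage has recoverable ground truth; its
defaults are the study conditions it emulates, not free dials.

- **Designs.** Experiment 1: 180-trial sessions, each of the 20 ISI ×
  delay cells exactly 9 times in pseudorandom order; 25 participants × 2
  sessions = 9,000 trials. Experiment 2: 300-trial sessions, 6 cells × 50;
  24 × 2 = 14,400 trials (the published total, 14,205, is not divisible
  by whole sessions; the nearest whole-session count is used).
- **Faces** are independent uniform draws from the wheel (the designs
  impose no constraints).
- **Response model.** response = target + bias + noise, rounded and
  wrapped; bias is a DoG of the inducer−target difference, parameterised
  directly by its half-amplitude per design cell (converted to α through
  the closed-form extremum) with generating width σ = 20 steps. The
  default amplitude map places attraction where the published fits found
  it (experiment 1: 3.6 steps at ISI 1 s/delay 1 s, 5.9 at ISI 1 s/delay
  6 s; experiment 2: 2.1 and 2.4 at the Face-2-target 1-s and 6-s delays)
  and zero elsewhere; no across-trial bias is generated by default.
- **Noise** is a discrete wrapped Gaussian (SD 15.28 steps, frozen from
  one bisection run of `calibrate_noise` targeting 72% classification
  accuracy; the default observer lands at ~73%, inside the published
  69–74% band). A von Mises kernel would serve equally; the wrapped
  Gaussian was chosen for its transparent small-σ calibration.
- **Lapses.** With probability 0.06 (experiment 1) or 0.025 (experiment
  2) the response is uniform on the wheel; half of the lapses also draw a
  response time above 15 s so both exclusion filters see traffic.
  Non-lapse response times are lognormal (median 4.3 s, shape 0.51,
  matching a mean near 4.9 s with SD 2.7 s). Together these reproduce the
  published filter-removal fractions (~4.1% and ~2.1%).

What the generator does **not** emulate: sequential dependencies in human
lapsing and response times, participant heterogeneity in noise or bias,
memory decay within the delay beyond the per-cell amplitude map,
perceptual similarity structure between specific face images, or
adjustment trajectories. Passing recovery tests therefore shows the
estimators are correct and calibrated for an observer of this class — not
that human data would satisfy the same error model.

## Validation studies (in the test suite)

- Geometry: exhaustive 141 × 141 brute-force distance oracle; exact
  category partition; rotation/relabel symmetry.
- Closed-form DoG extremum against dense-grid search, to 1e−9.
- Null calibration: eight simulated 9,000-trial experiments with zero
  amplitude — mean fitted half-amplitude ~0, CI significance rate ~5%,
  categorical index at baseline.
- Parameter recovery: true amplitudes {0, 2, 4, 6} at ~1,800 trials/cell,
  48 replicates — per-cell mean bias below 0.5 steps, bootstrap-CI
  coverage at nominal 95% (binomial floor 87%).
- Power pattern: attraction of 6.0 steps only at (ISI 1 s, delay 1 s) and
  (ISI 1 s, delay 6 s) — both cells detected with ≥90% power at the
  9,000-trial study size while the 18 null cells stay at the nominal
  false-positive rate. The 6.0-step effect size for this power study was
  set from an a-priori variance calculation (var(α̂) ≈ noise²/Σg²): the
  smaller published-scale effect (3.6 steps) has only ~85–89% power at
  ~430 trials/cell, so a pattern study demanding ≥90% detection must use
  an effect at the scale of the larger one (5.9).
- Filter contract: exact keep/drop decisions at the 15-s and ±60-step
  boundaries.

Problem sizes (replicate counts, 1,000-iteration bootstraps) were chosen
so each study's Monte-Carlo error is small against the quantity it
checks.

## Known limitations

- The half-amplitude estimator inflates slightly near its detection limit
  (basin selection under the global RSS minimum); see the fitting section.
- The exact constraint set of the original constrained minimisation this
  pipeline parallels is not published; the bounds here are this package's
  own declared defaults.
- BCa jackknife cost grows linearly in trials per cell; for very large
  pooled sets prefer the percentile method.
- The interface is a library plus numbered analysis drivers; there is no
  console entry point — `analysis/01_simulate.py` … `05_parameter_recovery.py`
  are the runnable surface.
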