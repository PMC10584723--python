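# sdfaces

Serial-dependence analysis for two-face continuous-report experiments on a
circular face-morph wheel.

In these experiments two faces (Face 1, then Face 2) are drawn from a
closed continuum of 141 morphed images (three anchor identities with 46
morphs between each pair). After a retention delay the observer adjusts a
probe face to reproduce a target face; the signed circular distance from
target to response is the adjustment error. *Serial dependence* is the
systematic pull of that error toward another recently seen face (the
"inducer" — the trial's other face, or a face from the previous trial).

The package implements the complete analysis chain for two designs —
experiment 1 (4 ISIs × 5 response delays, target always Face 2) and
experiment 2 (postcue chooses the target, 2 postcues × 3 delays) — plus a
synthetic observer so that every stage can be validated against known
ground truth (the original behavioural data are not publicly deposited).

## The model

Adjustment error *y* is modelled against the inducer–target difference *x*
(signed morph steps) with a derivative-of-Gaussian (DoG) bias curve

```
y(x) = α (x − µ) N(x; µ, σ)
```

where *N* is the normal density, σ sets the width of the bias, µ its
centre, and α its height; the curve's extremum magnitude
|α| e^(−1/2)/√(2π) — the **half-amplitude**, in morph steps — is the scalar
measure of serial dependence (positive = attraction toward the inducer,
negative = repulsion). Fitting is constrained least squares
(µ ∈ [−20, 20], σ ∈ [10, 70]); α enters linearly and is profiled out in
closed form, so the search is a deterministic global grid-plus-polish over
(µ, σ). Significance per design cell comes from a 95% bootstrap CI on the
half-amplitude (trial resampling, 10,000 iterations by default).

A nonparametric companion index avoids the DoG shape assumption entirely:
the wheel is partitioned into three 47-position prototype categories,
classification errors (response outside the target's category) are split
by the inducer's category, and the proportion of errors landing in the
inducer's own category — averaged over the three categories, minus the
33.33% chance baseline — measures categorical attraction. Classification
accuracy (response in the target's category) is reported alongside.

## Worked example

```python
import sdfaces as sd

wheel = sd.build_wheel()                       # 141 positions, anchors 0/47/94
cfg   = sd.SimConfig(experiment=1, seed=7)     # default synthetic observer
trials = sd.simulate_experiment(cfg, wheel)    # 9,000-trial table
report = sd.run_analysis(trials, experiment=1,
                         config=sd.AnalysisConfig(n_boot=2000, seed=1,
                                                  variants=("within_trial",)))
print(f"removed {report.removal_fraction:.1%} of trials")
sig = report.dog_within.query("significant")
print(sig[["condition", "n", "half_amplitude", "ci_low", "ci_high"]].round(2))
```

prints (seed 7 observer, seed 1 analysis):

```
removed 4.0% of trials
  condition    n  half_amplitude  ci_low  ci_high
3    (1, 6)  432            5.39    3.16     8.67
```

The default observer generates attraction of 3.6 steps at (ISI 1 s,
delay 1 s) and 5.9 steps at (ISI 1 s, delay 6 s) and nothing elsewhere.
The larger effect is detected (estimate 5.39, CI excluding zero); the
3.6-step cell sits near the detection limit at ~430 trials/cell (~60–85%
power, depending on the draw) and is missed at this seed — which is why
the validation suite's power study uses a 6-step effect. The numbered
scripts under `analysis/` run the full sequence — simulate, within-trial
fits, across-trial fits, categorical index, parameter recovery — and
write their tables under `results/`.

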