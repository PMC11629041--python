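# Methods

## Problem and pipeline

`plantargait` models functional assessment of people with knee
osteoarthritis (KOA) from in-shoe plantar pressure. Two clinic tests — the
40 m fast-paced walk test (40mFPWT) and the timed up-and-go test (TUGT),
both completion times in seconds — are predicted from gait features
extracted out of bilateral 8-sensor insole recordings sampled at 20 Hz.
The pipeline runs in five stages: waveform simulation (or recorded input),
gait-cycle segmentation, feature extraction, stepwise feature selection,
and regression modelling with ensembles.

## Synthetic waveform model

Walking produces, per foot and cycle, a bimodal total vertical ground
reaction force (VGRF): a weight-acceptance peak shortly after heel strike,
a mid-stance valley, a push-off peak, and an unloaded swing phase. The
generator interpolates the planted control points — (heel strike, 0),
(t1, peak1), (mid, valley), (t2, peak2), (toe-off, 0) — with a monotone
PCHIP spline, so the sampled curve reproduces the planted amplitudes
exactly at the landmark samples and is bimodal in between. The total is
then split across the 8 sensors with smooth Gaussian region weights (heel
loaded around the first peak, forefoot around the second, midfoot bridging
the valley) and fixed per-sensor shares within each region; the channel
sum therefore equals the planted total identically.

Defaults (per fraction of body weight, %BW): cycle duration 1.05 s, stance
fraction 0.62, peak times at 15% and 48% of the cycle, peak amplitudes
1.10 and 1.05 %BW, valley 0.75 %BW, 60 cycles per recording — values
typical of slow adult walking. The right foot lags the left by half a
cycle, so double-limb support exists whenever stance exceeds half the
cycle. Cycle-to-cycle variability is a per-cycle Gaussian scaling of
duration and amplitude (SD 0.02 by default), *shared* between feet so that
left/right differences are controlled solely by the asymmetry parameter
(which scales the right foot's amplitudes and stance fraction). With
asymmetry 0 the feet are identical up to the phase offset; with jitter 0
all cycles are identical — the two degenerate cases that anchor the
symmetry-index and SD-feature tests.

Two discretization guards matter at 20 Hz: the push-off peak is kept at
least 2 samples before toe-off (otherwise it cannot be an interior local
maximum of the sampled curve), and a recording holds 60 cycles so the
50-cycle analysis window survives the occasional cycle excluded as
unimodal after rounding.

What the generator does **not** emulate: sensor noise and drift, turning
strides in a corridor walk, fatigue trends, KOA-severity-specific waveform
shapes, and ground-truth coupling between waveform shape and disease. A
green test suite therefore shows the *algorithms* are correct and the
planted signal is recoverable — not that the models reach any particular
accuracy on patients.

## Cohort and label model

A synthetic cohort (default n=92) samples physical characteristics from a
representative KOA population (age 63 (8.4) y, height 158 (7.9) cm, weight
61 (10.5) kg) and per-participant waveform parameters (cycle duration SD
0.08 s, stance fraction SD 0.03, half-normal asymmetry scale 0.05). Labels
are linear in gait parameters and age with Gaussian noise:

    y = intercept + Σ βk (xk − ref_k) + N(0, σ)

with intercepts 28.61 s (40mFPWT, σ=2.5) and 11.39 s (TUGT, σ=1.2) and
positive coefficients on cycle duration, stance fraction, asymmetry and
age — slower, more asymmetric, older walkers take longer. Coefficients
were chosen once so the simulated label spread is near the cohort values
the intercepts come from; the linear form is deliberately the simplest
structure that makes recovery experiments well-posed (which parameters
carry signal is returned as a ground-truth table).

## Segmentation

The detection threshold is 5% of the recording's maximum total VGRF, with
a 2-sample hysteresis on the rising crossing. Heel strike is the first
sample of a persistent rise; toe-off the first subsequent sample at or
below threshold; the cycle ends at the next heel strike (trailing
incomplete cycle discarded). Within stance, the two largest interior local
maxima (ties to the earlier sample) are the force peaks and the earliest
minimum between them the valley; stances with fewer than two interior
maxima are excluded with a warning rather than fabricating a valley. All
indices are 0-based with half-open `[start, end)` spans, and every
returned cycle satisfies heel strike < peak1 ≤ valley ≤ peak2 < toe-off ≤
cycle end.

The analysis window drops the first 2 detected steps per foot and keeps
the next 50 left/right-adjacent cycles. A pair is adjacent when the right
heel strike falls within the left cycle span or the stance intervals
overlap; right cycles that started before the current left cycle are
skipped, which keeps the pairing aligned across gaps left by excluded
cycles.

## Features

Per cycle pair, 110 features: 54 per foot (15 peak-pressure, 25
pressure-gradient, 5 temporal, 2 pressure-time-integral, 7
centre-of-pressure) plus single- and double-limb support times. Details
that are conventions rather than consequences:

- Regional peak pressure (e.g. `L_1-4_PPP`) is the maximum of the *summed*
  regional series, not the sum of per-sensor maxima.
- The off-loading rate is stored signed (stance-end pressure minus second
  peak over the elapsed time; negative in normal gait).
- PTIs are trapezoidal integrals of the total curve, heel strike → first
  peak and heel strike → toe-off, in %BW·s.
- COP uses sensor coordinates normalized by foot width/length (pooling
  across shoe sizes) and only stance samples above the detection
  threshold; resultant distances are measured from the stance-mean COP
  point.
- Undefined ratios (zero denominators, unloaded stances) propagate as NaN,
  are skipped by the 50-cycle mean/SD, and are mean-imputed with
  *training-split* statistics just before modelling.

Participant level: 50-cycle means of all 110, sample SDs (ddof=1, suffix
`STD`) of the 108 single-foot features, the Robinson symmetry index
SI = |L−R| / (0.5(L+R)) × 100 of the 54 single-foot means (NaN when the
mean is zero), and weak-foot copies (prefix `W`) of the 54 means and 54
SDs of the foot with larger anterior-posterior COP variability
(`ycop_std`; ties go left). With age, height, weight and BMI this gives
the 384-column vector: 30 PPP + 50 PG + 12 temporal + 4 PTI + 14 COP + 54
SI + 108 STD + 108 weak-foot = 380 gait features + 4 physical.

## Feature selection

All selection statistics are computed from the training split only; the
entry point takes the full table plus training indices so leakage can be
asserted by perturbing held-out rows.

1. Spearman filter: drop features with |ρ| < 0.2 against the label
   (inclusive at the threshold; constants dropped as undefined).
2. mRMR, MID variant for a continuous target: greedy score
   |pearson(x, y)| − mean |pearson(x, selected)| on z-scored (training
   statistics) features; at most k features, k defaulting to the
   training-set size. With redundancy weight 0 this degenerates to top-k
   relevance, which the tests exploit as an oracle.
3. Floating wrapper (SFFS from the empty set or SBFS from the full set)
   with conditional add/remove steps, scored by mean 5-fold CV MAE of a
   seeded random-forest base model; the conditional step must *strictly*
   improve the best score recorded at the target size, which guarantees
   termination. The best subset over all visited sizes wins.

The PCA benchmark trains the same base model on leading principal
components (explained-variance threshold 0.95 by default) with identical
CV folds, giving a like-for-like comparison of stepwise selection against
plain dimensionality reduction.

## Models and evaluation

Six individual regressors: linear regression, RBF-kernel SVR (standardized
inputs), random forest, AdaBoost, XGBoost and LightGBM. Hyperparameters
are tuned by seeded randomized search (documented log-uniform/integer
spaces; budget = number of draws) scored by 5-fold CV MAE on shuffled,
unstratified folds; reported CV metrics are per-fold means at the chosen
parameters.

The stacked model uses the four tree-based regressors as first level. In
each outer CV fold, inner 5-fold out-of-fold predictions of the members
form the n×4 matrix that trains the second-level model (linear regression
or RBF SVR); members are refit on the outer-training rows before
predicting the outer-validation rows, so no member ever predicts a sample
it saw in training. The final model repeats the out-of-fold construction
on all data.

Metrics: MAE (s), MAPE (100·mean |e|/y, %; errors on zero labels), RMSE
(s). The baseline predictor is the training-label mean; the relative index
RI sums the three per-metric relative improvements over the baseline
(RI=0 for the baseline itself). SAE averages member predictions equally;
WAE weights them by RI proportions — members with RI ≤ 0 are excluded
(their proportional weight is undefined) and WAE errors only when no
member has positive RI. The 33% holdout split uses scikit-learn's
`train_test_split` (test size rounded up), so 92 participants split
61/31.

## Problem sizes in the test and acceptance runs

The suite exercises the pipeline at sizes chosen for desk-scale
completeness: unit oracles on 100 random cycles; cascade recovery on
20-feature matrices (n=60, 3 informative, 20 seeded repetitions, ≥2/3
recovered required in ≥80%); pipeline-level RI recovery on 20 synthetic
cohorts of n=100 against shuffled-label controls (win required in ≥90%);
and a single seeded stepwise-vs-PCA comparison (n=80, 30 features). The
wrapper's base forest uses 20–50 trees in these experiments; pipeline
defaults are larger.

## Known limitations

- 20 Hz sampling quantizes landmarks to 50 ms; temporal features have
  coarse resolution and the generator's discretization guards reflect it.
- The SI and weak-foot formulas follow the standard definitions
  (Robinson index; anterior-posterior COP variability); other published
  variants exist and the weak-foot rule is configurable in code.
- The synthetic cohort is not a clinical dataset; model error magnitudes
  on it are not comparable with patient-cohort results, and the package
  deliberately reports only recovery/arithmetic claims as acceptance
  criteria.
- Turning strides are not modelled or removed; all detected cycles are
  treated uniformly.
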