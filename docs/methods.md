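# Methods

## Calibration core

The regression engine is PLS1 computed by NIPALS deflation on
mean-centered X and y. No variance scaling is applied: absorbance
channels share a unit, and autoscaling would inflate the noise-only
channels the selector exists to remove. Deflation stops early if the
covariance X'y (or a score norm) falls below 1e-12 — e.g. on
rank-deficient or all-constant predictor blocks — in which case the
remaining components are zero and `n_lv_eff < n_lv` is recorded; an
all-zero X therefore yields the mean model rather than an error. At full
column rank PLS1 reproduces ordinary least squares, which the test suite
uses as an independent oracle (together with scikit-learn's NIPALS
implementation).

Prediction error metrics are the usual RMSE and R² = 1 − SS_res/SS_tot
with SS_tot about the mean of the observed values; R² errors out on a
zero-variance reference rather than returning a spurious value.

## Monte Carlo cross-validation

Model selection and wrapper fitness both use MCCV: `n_splits` random
calibration/validation splits of the training block, each fitting on a
`calibration_fraction` of the samples. Defaults are 50 splits at 0.8; both
are exposed in `CVConfig`. The RMSECV pools the squared residuals of all
held-out samples across splits before taking the root — invariant to
unequal holdout sizes, unlike averaging per-split RMSEs. If a split's
calibration part cannot support the requested latent-variable count, the
count is clamped to the feasible maximum for that split and a warning is
emitted; failing mid-optimization would be worse than a slightly
conservative fitness. The latent-variable count is chosen as the minimizer
of RMSECV over 1..max_lv, ties going to the smaller count.

## Discretized grey wolf optimizer

Continuous pack positions start uniform in [0, 1]. Per iteration t (1 to
t_max) the convergence coefficient is a = 2(1 − t/t_max); every wolf —
leaders included — moves toward the α/β/δ positions frozen at iteration
start (synchronous update), with r1 and r2 drawn independently per wolf,
per leader and per coordinate. Several choices here resolve genuine
ambiguities in how binary grey-wolf selectors are usually described:

- **Transfer function.** Discretization uses the standard binary-swarm
  construction: a steep logistic σ(x) = 1/(1+exp(−10(x−0.5))) mapped to a
  probability and thresholded against a fresh uniform draw. Slope and
  center are configurable, and a deterministic ≥ 0.5 cutoff mode exists
  for reproducibility studies.
- **No clipping.** Positions may leave [0, 1]; the logistic saturates, so
  excursions simply pin the corresponding bit.
- **Greedy memory.** Each wolf compares its new fitness with its previous
  one and keeps the better position (ties accept the move). This makes
  the α trajectory non-increasing — a structural invariant the tests
  assert on every run.
- **Fitness caching.** The MCCV splits are drawn once per run, making
  RMSECV a pure function of the mask bits; evaluations are cached by bit
  pattern. An all-zero mask gets a large finite penalty (1e6) instead of
  a PLS call, steering the pack away smoothly.

Defaults t_max = 100 and n_wolves = 75 reflect where iteration-number and
pack-size sweeps typically plateau on data of the benchmark's size; both
are plain config fields, and the sweep helpers (`sweep_iterations` via
trajectory slicing of one long run — valid because the trajectory is the
running best — and `sweep_wolves` by independent runs) exist to re-derive
them on any dataset.

## Baseline selectors

**MCUVE-PLS** fits PLS on `n_mc` (default 500) random 80% sub-calibration
sets and scores channel i by the stability mean(b_i)/sd(b_i) of its
regression coefficient. Channels are ranked by |stability|; candidate
kept-counts (default 10..200 step 10, clipped to the channel count) are
scanned by RMSECV and the best count wins. A coefficient with exactly zero
spread across resamples (e.g. a constant-zero channel) gets a signed
sentinel stability with a warning.

**RT-PLS** compares each |coefficient| with its null distribution under
`n_perm` (default 199) response permutations, using the add-one estimator
p = (1 + #{|b_perm| ≥ |b|})/(n_perm + 1), which can never return zero.
Channels with p ≤ 0.05 are kept; if none pass, the single smallest-p
channel is kept so a model always exists. The permutation RNG stream is
decoupled from the CV stream so the two variance sources are independent.

## Synthetic data generator

The generator emulates the statistical structure of quaternary blend-oil
UV-Vis measurements: 102 samples on the 601-point 200–800 nm grid, with
one bulk component spanning 0–100% (2% grid), two fillers capped at
98%/96% splitting the remainder, and a minor component at 0–10% (0.2%
grid); every composition sums to exactly 100% g/g. Absorbance is the
Beer–Lambert mixture of four Gaussian-peak pure spectra sharing the
visible cluster near 427/452/478 nm with few-nm per-component shifts plus
component-specific UV features — collinear but distinguishable, so no
single channel identifies a component. Gaussian noise has sd 0.02 AU,
multiplied by 5 inside 200–350 nm. The base level was set so that (a) the
UV noise is plainly visible against 0.5–0.9 AU peaks, as in real
measurements of this kind, and (b) carrying uninformative channels
measurably inflates RMSECV — without that selection pressure there is
nothing for a wavelength selector to find. Baseline offsets are nearly
equal across components (0.019–0.022 AU) so the planted information lives
in the absorption bands, and the featureless red tail stays genuinely
uninformative.

The ground-truth informative mask flags wavelengths where the
between-component contrast of the pure spectra (max − min) exceeds 3× the
local noise sd (threshold configurable). It exists purely for testing:
real datasets have no such ground truth.

What the generator does **not** emulate: scatter and stray-light effects,
instrument response functions, wavelength-dependent pathlength or
temperature drifts, and the true (unpublished) pure-component spectra of
edible oils. Passing tests therefore demonstrate that the selectors
behave correctly on data with the assumed linear-mixture structure, not
that they will match any particular laboratory dataset's numbers.

## Benchmark protocol and problem sizes

`compare_methods` reruns each stochastic selector over independent seeds
(selector and CV splits both re-seeded per run), refits on the training
set, predicts the independent prediction set, and reports mean/S.D. of
RMSEP and R² plus min/mean/max selected-channel counts; full-spectrum PLS
runs once with S.D. exactly 0. Summary JSON excludes wall-clock fields so
a fixed base seed reproduces it byte for byte; timing is recorded but
never asserted on.

The test suite and the acceptance script run the selector benchmarks at a
reduced scale chosen as a sensible desk-scale default: the full 200–800 nm
range at a 5 nm step (121 channels), 102 samples, 20 wolves, 40–60
iterations and 12 MCCV splits. Structural checks (grid size, 51/51 split,
noise-ratio calibration) run at the full 601-channel scale. The 8-variable
exhaustive-search equivalence uses 255 mask enumerations per seed, and the
planted-mask enrichment test scores the summed overlap of 20 independent
runs against 2000 size-matched random masks.

## Known limitations

- Wrapper fitness on fixed CV splits can overfit those splits; a handful
  of genuinely uninformative channels typically survive in the selected
  masks, which is why recovery is asserted as enrichment, not equality.
- The sigmoid-threshold discretization is a reconstruction of common
  binary-GWO practice; other transfer functions would change the
  exploration/exploitation balance.
- PLS1 only (one response at a time); no spectral preprocessing (SNV,
  derivatives, smoothing) is applied or provided.
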