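# Methods

## The pairwise forecasting model

Longitudinal cohort records are short (1–10 visits), irregularly spaced and
sparsely observed, so the package does not model the sequence of
measurements as a time series. Instead each ordered pair of visits (i, j)
with month_i < month_j of one participant contributes a supervised sample:
the input is a snapshot of the participant's state at visit i — last
diagnosis, current cognitive and volumetric measurements, least-squares
slopes of past measurements, and static covariates — together with the time
delay Δt = month_j − month_i; the target is the outcome observed at visit j.
With λ the static covariates and g_t the outcome, the model is
g_t = f(λ, g_{t−Δt}, Δt) + ε_t, and f is learned by a random forest. All
forward pairs are used, not only consecutive visits: short series then still
populate many time separations, and Δt itself is a feature, so a single
model covers horizons from one month to seven years. The error term ε_t is
absorbed by the learner; no distributional assumptions are made about the
sampling process or the measurement noise.

Four models are trained, one per target:

- diagnosis (3-class: NL, MCI, AD) — classification;
- ADAS-13 — regression;
- ventricle volume and intracranial volume — two separate regressions whose
  ratio gives the normalised atrophy output, with the ratio interval formed
  as [vents_lo/icv_hi, vents_hi/icv_lo].

Feature sets per target are fixed (they reproduce an established operating
point rather than being re-selected at run time): the diagnosis set is
{DX, AGE, GENDER, APOE, MMSE, CDRSB, FAQ, RID, MIDTEMP, TIME_DELAY, ΔMMSE,
ΔHIPPOCAMPUS, ΔVENTRICLES}; ADAS-13 adds ADAS13 and ΔADAS13; the two volume
models use only the volume itself, its slope, and TIME_DELAY.

Feature engineering choices, where the convention was genuinely open:

- **MMSE** enters binarised at 26 with raw ≥ 26 → 1; the threshold is the
  conventional normal-cognition cut, and the direction (≥ 26 meaning
  unimpaired) is the package's choice.
- **Slope features (Δ-prefixed)** are ordinary least-squares slopes (units:
  value per month) over *all* observations at months ≤ the source visit —
  not the last difference quotient. OLS is robust to irregular spacing and
  reduces to the difference quotient for two points; with fewer than two
  observed points the slope is missing. Using only months ≤ source
  guarantees no information leaks from the destination side of a pair
  (verified by truncation recomputation in the tests).
- **AGE** is the age at the source visit (baseline age + month/12), so Δt
  remains the sole time-separation signal.
- **RID**, the participant identifier, is a numeric feature. It lets trees
  carve out individual-specific behaviour for participants present in
  training; it is informative exactly because the evaluation participants'
  own histories are in the training set.
- **Encodings**: DX as 0/1/2 (NL/MCI/AD), gender as 0/1 (female/male) —
  fixed ordinal codes keep the forests deterministic under a seed.
- **Missing values** are filled from the training pairs: median for numeric
  features, mode for categorical ones, and 0 for missing slopes (no observed
  trend). Model-based imputation is deliberately avoided — the method's
  point is to need no distributional assumptions.

Training uses only participants with at least `min_points = 4` visits;
shorter series yield too few pairs to constrain f and degrade the fit.

## Forests

Standard bagged decision trees (scikit-learn): bootstrap samples of size n
per tree, ⌈√p⌉ of the p features considered at each split, growth stopped at
a minimum leaf size. Defaults are 60 trees and a minimum leaf of 5, the
operating point found by out-of-bag error minimisation over the grid
{20, 40, 60, 80, 100} × {1, 5, 10, 25}; `tune()` re-runs this search (ties
prefer the smaller leaf, then the smaller ensemble). OOB error is the
misclassification rate for the classifier and mean squared error for
regressors.

Prediction outputs:

- **Class probabilities** are the ensemble average of per-tree leaf class
  proportions (not majority votes): smoother scores, which matters for
  ranking metrics like mAUC.
- **50% prediction intervals** are the 25th/75th percentiles (linear
  interpolation) of the per-tree predictions, widened if necessary to
  contain the ensemble-mean point estimate. This is a deterministic,
  assumption-free construction; it is a heuristic, and the coverage tests
  only check calibration empirically.
- **Variable importance** is OOB permutation importance: for each tree, the
  increase in its out-of-bag error when one feature's values are permuted
  among the OOB samples, averaged over trees and divided by the standard
  deviation across trees. A single tree (or a zero-variance increase) falls
  back to the raw mean; never-used features score 0. The in-bag index
  replication matches scikit-learn's bootstrap draw exactly, so the OOB
  masks are the true ones.

Reproducibility contract: identical pairs + config + seed give bit-identical
predictions; every stage seed is derived from the single run seed.

## Matched evaluation set

To validate during training on series that look like the held-out history
cohort, each history participant is matched to a training participant with
equal gender, equal ApoE4 count, baseline age within 5 years, and the same
diagnosis at the first and last history-phase visit; among candidates the
closest history-phase series length wins. Matching is greedy in ascending
history RID, without replacement, with length ties broken by the lowest
candidate RID — the ordering and tie rules are the package's choices, fixed
for determinism. Participants with no eligible candidate stay unmatched.

## Evaluation metrics

- **mAUC** (Hand–Till): for an ordered class pair (i, j), rank the pooled
  samples of the two classes by the probability assigned to class i; with
  S_i the sum of midranks of class-i samples, Â(i|j) = (S_i − n_i(n_i+1)/2)
  /(n_i n_j); the pair score is (Â(i|j)+Â(j|i))/2 and mAUC averages the
  three unordered pairs. Midranks make all-tied input score exactly 0.5.
  Pairs missing a class are skipped.
- **BCA**: per class one-vs-rest, the mean of TPR and TNR, averaged over the
  classes present in the true labels (predictions by argmax, ties to the
  lower class index).
- **MAE**: mean absolute error of the point estimates.
- **WES**: Σ w_k |e_k| / Σ w_k with w_k the inverse interval width. The
  normaliser makes WES comparable to MAE (equal widths ⇒ WES = MAE).
  Zero-width intervals get weight 1/ε with ε = 10⁻⁶ of the truth SD.
- **CPA**: |j − 0.5| where j is the fraction of truths inside the 50%
  interval, boundaries inclusive; 0 is perfect calibration.

Truth visits are matched to forecast rows per participant by nearest
forecast month within a ±3-month window (ties to the earlier month); the
window and the nearest rule are the package's choices.

## The synthetic cohort generator

The simulator exists so the whole pipeline is testable with known ground
truth; it emulates the structure of an ADNI-style cohort, not its full
covariance.

- **Progression** is a forward-only three-state continuous-time Markov chain
  NL → MCI → AD with exponential sojourns. Base intensities are
  λ(NL→MCI) = 0.004/month and λ(MCI→AD) = 0.008/month, scaled ×1.5 per ApoE4
  allele and ×1.2 per decade of baseline age above 75 — values chosen once
  to put 7-year conversion fractions in the broad range reported for MCI
  cohorts; they are configuration, not empirical claims.
- **Demographics**: age ~ N(75, 6²) clipped to [55, 90]; 60.9% male; ApoE4
  allele-count probabilities 0.70/0.27/0.03; baseline diagnosis mixture
  0.25/0.50/0.25 (NL/MCI/AD), the registration ratio of the cohort being
  emulated.
- **Visits** follow the nominal schedule 0, 6, 12, 18, 24, 36, 48, 60, 72,
  84 months with uniform ±2-month jitter (baseline fixed at 0) and a 15%
  per-visit permanent dropout, giving the right-skewed series-length
  distribution typical of such studies.
- **Biomarkers** (MMSE, ADAS-13, CDRSB, FAQ, ventricles, ICV, middle
  temporal gyrus, hippocampus): per-participant Gaussian baseline + a
  baseline-state offset + state-dependent drift integrated over the time
  spent in each state + Gaussian noise, clipped to plausible ranges; ICV is
  constant up to noise. Missingness is MCAR per variable (5–15%), and the
  diagnosis itself is missing at 3% of visits.
- **Split**: ~6.3% of participants (the 110/1737 ratio of the emulated
  leaderboard) with visits on both sides of the month-36 boundary and not
  AD at their last pre-boundary visit contribute pre-boundary visits to the
  "history" cohort and post-boundary visits to "test"; everyone else trains.

What passing tests on this generator do *not* show: real cohorts have
informative missingness, correlated biomarker noise, diagnostic
misclassification and measurement batch effects, none of which are
simulated; results on synthetic data demonstrate correctness of the
machinery and recoverability of planted dynamics, not clinical performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 120–500
participants with forecast horizons every 1–12 months up to 84; these sizes
give on the order of 10⁴ training pairs and ~100 held-out evaluation points,
enough for the recovery checks (e.g. frozen-dynamics accuracy ≥ 0.95,
progressive-cohort mAUC above a carry-forward baseline) while keeping runs
in seconds. Calibration checks use n = 2000 (conversion fraction vs the
closed-form 1 − e^(−λt)) and n = 5000 (demographics), both within 3
standard-error bands.

Degenerate inputs are handled explicitly: single-class training collapses to
a certainty predictor; constant regression targets give zero-width intervals;
coincident months make a slope undefined (missing); empty OOB sets drop a
tree from the importance average; an all-skipped mAUC (fewer than two
classes) raises.

## Known limitations

- Prediction intervals are ensemble-spread heuristics; no coverage guarantee.
- RID as a feature only helps participants seen in training; for entirely
  new participants the model falls back on the remaining features.
- Forests cannot extrapolate beyond the training target range, so long-term
  volumetric forecasts saturate.
- Greedy matching is order-dependent by construction; it is deterministic
  but not optimal in the bipartite-matching sense.
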