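# Methods

## Labeling model

The labeler treats device non-use as a missing-data problem whose labels
must themselves be inferred, one user at a time. Its two assumptions are:

1. **Extreme quadrants are trustworthy.** Days on which both the device-usage
   summary (c^Z) and the sensor-activity summary (c^W) are low — below the
   θ_lower quantile on both axes — can be taken as non-use days with high
   confidence; days high on both axes (above θ_upper) as use days. Mixed
   quadrants are ambiguous (an engaged user whose sensor uploads lag, or a
   sensor firing while the phone sits untouched) and are deliberately left
   to stage 2.
2. **Proximity in the usage/activity plane carries label information.** A
   day that looks, in (c^Z, c^W), like confident non-use days probably is
   one. Stage 2 operationalizes this with a k-nearest-neighbor majority vote
   among the prototypes under Euclidean distance.

The two stages convert an unsupervised problem into a semi-supervised one:
stage 1 manufactures partial labels from the data's own extremes, stage 2
propagates them.

### Feature space

PCA is computed on the correlation scale: columns of `Z` (and of `W` when
S > 1) are standardized to mean 0 and unit sample variance (denominator
n − 1) before the decomposition, because usage variables mix incommensurate
units (counts, variances). The first-PC score vectors are then themselves
rescaled to unit variance so that Euclidean distance in stage 2 weighs the
two axes equally, and each axis is sign-oriented so that it correlates
non-negatively with the row-sum of its standardized block — i.e. larger
coordinates always mean more use/activity, with sign +1 on exact ties. A
single-column block passes through as its standardized self; this makes the
one-column shortcut exactly consistent with the multi-column path and keeps
distances unit-free. Days with any technically absent `W`/`Z` value are
excluded from the feature space and labeled `technical_missing`, since a PCA
cannot consume absent values and such days are a different phenomenon
(device off) from inferred non-use.

Constant columns standardize to all-zeros rather than raising; a column is
"constant" when its maximum equals its minimum exactly, which also guards
against summation rounding producing a spurious tiny variance. A fully
constant block is a hard error: no usage signal exists.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| θ_lower, θ_upper | 0.30, 0.70 | quantile thresholds bounding the prototype quadrants; tighter bands (0.20/0.80) produce fewer, more extreme prototypes and raise sensitivity at the cost of specificity, wider bands the reverse |
| k | 5 | stage-2 neighborhood size; small and odd to avoid most voting ties, always validated so that k/2 ≤ min(class sizes) and k ≤ total prototypes |
| minimum T | 10 | below ~10 usable days the 30/70% quantile construction cannot reliably populate both prototype quadrants |

Quantiles use linear interpolation: with sorted values v(1..n) and
h = (n−1)θ + 1, the quantile is v(⌊h⌋) + (h−⌊h⌋)(v(⌊h⌋+1) − v(⌊h⌋)).
Prototype membership uses strict inequalities, so points tied exactly with a
quantile stay unlabeled.

### Determinism and tie-breaking

All of stage 2 is deterministic: a split vote goes to the label of the
single nearest prototype; if both labels occur at exactly the nearest
distance, to `missing` (the conservative choice for data-quality screening);
distance ties at the k-th neighbor are broken by lower point index.
Prototype labels are never overwritten by the KNN stage. An empty prototype
class is a hard error with an actionable message (widen the band, monitor
per-class prototype counts) rather than a silent fallback — threshold choice
is the practitioner's lever and should be driven by those counts.

When a user has several passive variables, each column of `X` is labeled
separately. By default all columns share one feature space (one phone, one
set of usage proxies); per-column `W`/`Z` mappings are available for
passive measures backed by different sensors.

## Synthetic panel generator

The generator emulates a smartphone step-count study at hourly resolution
and aggregates to days. Per user, an activity level L_A and usage level
L_U (both in [0, 1]) control everything:

- daily truth: non-use with probability 1 − p_use, p_use = 0.15 + 0.7·L_U;
- time-of-day weights ω_h: 0.2 in [0, 6), 1.0 in [8, 22), 0.6 otherwise;
- hourly device use U_h ~ Bern(min(1, 1.2·L_U·ω_h)) on use days,
  Bern(0.05) on non-use days (a phone left at home still gets touched
  occasionally);
- hourly activity A_h ~ Bern(min(1, L_A·ω_h)); true steps per active hour
  ~ Poisson(600·L_A); captured steps only in hours with U_h = 1 — the
  duty-cycling downward bias, so captured ≤ true holds exactly by
  construction;
- daily aggregates: uploads UP = Σ U_h·Bern(0.9); screen unlocks
  SU = Σ U_h·Poisson(2·L_U·ω_h); notifications DN ~ Poisson(20·L_U)
  *independent of the day's truth* (notifications arrive whether or not the
  phone is carried), deliberately a weak-signal column that exercises the
  PCA; battery variance BV ~ Gamma(2, 1 + 4·Σ U_h/24); a second passive
  measure active_minutes = Σ 60·A_h·U_h·Beta(5, 2), correlated with steps
  through the shared activity process.

All constants live in one overridable `SimParams` block. Randomness flows
through numpy's PCG64 (`default_rng`); every entry point takes an explicit
seed, and grid cells are sub-seeded from `(seed, cell_row, cell_col, rep)`
via `SeedSequence`, so any single panel is reproducible in isolation. If a
drawn truth vector is single-class (possible only at tiny T or extreme
L_U), the user is redrawn from a spawned sub-seed so both evaluation
metrics are defined.

What the generator does *not* emulate: weekday/weekend structure, serial
correlation in behavior across days, device swaps or OS-level changes in
duty-cycling policy, sensor error bursts (the high-activity/low-usage
quadrant arises only through random thinning), and any cross-user
correlation beyond shared parameter values. Passing tests therefore show
that the pipeline behaves correctly under a clean, stationary
use/non-use mixture — not that real panels, with their messier ambiguous
quadrants, will yield the same operating characteristics. In particular,
this generator separates the two classes more cleanly than real phone data
would, which inflates every method's sensitivity in the grid experiment;
the grid's qualitative structure (per-user thresholds adapting across
behavior profiles, zero-removal degrading at low activity) is the
meaningful output, and the acceptance checks against an external reference
band treat the absolute level accordingly as a soft comparison.

## Baselines

Zero-removal labels a day missing exactly when the passive value is 0 — the
threshold-free limit of the common fixed-cutoff practice. The one-class SVM
(RBF kernel, ν = 0.10, bandwidth 1/(n_features·variance), scikit-learn's
`gamma="scale"`) is trained on a pooled sample of 300 user-days of known
non-use-free status drawn across all users of a replicate, features `W`∥`Z`
standardized by training-row statistics, and evaluated on all remaining
days. ν and the bandwidth rule are this package's defaults, exposed in
`OcsvmParams`. The asymmetry is intentional and preserved: the SVM is a
*global* model consuming oracle labels unavailable in practice, while the
two-stage labeler is per-user and fully unsupervised.

## Evaluation conventions

Missing is the positive class: sensitivity = fraction of truth-missing days
labeled missing, specificity = fraction of truth-non-missing days labeled
non-missing. (The opposite naming also circulates; this package uses the
convention under which "high sensitivity" means unreliable days are caught,
which is the property that matters for data cleaning.) Metrics with an
empty truth class are reported as undefined, never 0. Grid-cell metrics are
aggregated across replicates by pooling confusion counts, not averaging
ratios — robust when single replicates have few truth-missing days and
exactly equal to summing per-replicate confusion matrices.

## Imputation

Cells labeled missing (or technically missing) are blanked and imputed with
an iterative random-forest scheme: initialize with column means, cycle
variables from least to most missing, refit a 100-tree forest per variable
per cycle (other variables as predictors), re-predict that variable's
missing cells, and stop when the relative change statistic
Σ(new − old)² / Σ new² over imputed cells first increases — returning the
previous iterate — or at 10 cycles. *Within-user* fits one model per user;
*across-users* stacks all users and appends per-user observed means of each
variable as covariates, letting the forest borrow structure across users
without losing individual levels. Observed cells are never altered.

Masking for evaluation: MCAR blanks observed cells independently at the
target rate (default 0.225, the midpoint of the conventional 20–25% band);
MAR blanks cell (t, j) with probability expit(α_j + z_t), where z_t is the
standardized driver (unit slope — one interpretable knob) and α_j is
calibrated per column by Brent root-finding (tolerance 1e−6) so the
expected marginal rate equals the target. A constant driver degenerates
exactly to MCAR. NRMSE uses the population-variance denominator (n), which
makes mean imputation score exactly 1 — a clean calibration point — and is
computed on the masked-then-imputed cells only, against the held-out truth.
A multilevel Bayesian imputer for the time-series correlation structure is
out of scope here; the random-forest routes are the supported methods.

## Problem sizes

The bundled experiments run at sizes chosen to keep the full suite fast on
a laptop while leaving Monte-Carlo noise well below the asserted margins:
the grid experiment uses 100 replicate 100-day panels per cell (pooled
counts of ~360,000 user-days overall), masking-rate checks use 10,000
cells, and imputation comparisons use 6 users × 60–150 days. The threshold
trade-off check pools 4 cells × 100 replicates per threshold setting with a
0.01 assertion margin.

## Known limitations

- Threshold and k selection remain manual; the package surfaces prototype
  counts as the tuning signal but implements no automatic selector.
- The labeler is strictly per-user; no information is borrowed across users
  at the labeling stage (only the across-users imputer does that).
- Alternative distance functions (Mahalanobis, density-based), posterior-
  probability voting, and bivariate-quantile prototype regions are not
  implemented.
- The KNN stage is O(unlabeled × prototypes) per user — fine at daily
  resolution (hundreds of days), not tuned for finer time grids.
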