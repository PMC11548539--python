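# twospamh

Two-stage unsupervised inference of device non-use ("missing") labels for
passively sensed mobile-health data, with a simulation study, comparison
baselines and an imputation-evaluation harness.

## The problem

Smartphones and wearables record behavioral measures — daily step count,
sleep duration, time in conversation — passively, without user input. But a
phone left on the nightstand records zero steps, and duty-cycled sensors
record intermittently, so the recorded values systematically *understate*
true behavior on days the device was not carried or worn. Whether the device
was in use on a given day is unknown to the analyst, and use patterns differ
across users, so fixed cutoffs ("drop days below 500 steps") are not
personalized and mislabel both active and sedentary users. This package
treats device non-use as a missing-data problem with unknown missing labels
and infers those labels per user, so that unreliable days can be excluded or
imputed before any downstream analysis of behavioral trajectories.

## The algorithm

For one user, let `X` (T×P) hold daily passive measures, `W` (T×S) sensor
activity (e.g. number of daily uploads to the server — a proxy for the
sensor recording), and `Z` (T×D) device-usage variables (screen unlocks,
battery variance, notifications — proxies for engagement). The output is a
label matrix `M`, same shape as `X`, with entries `missing` / `non_missing`.

**Stage 1 — prototype selection.** Each day t is embedded as a point
f_t = (c_t^Z, c_t^W), where c^Z and c^W are the first principal components
of the column-standardized `Z` and `W` blocks (a single column passes
through as its standardized self), each axis rescaled to unit variance and
sign-oriented so larger values mean more use. With quantile thresholds
(θ_lower, θ_upper) = (0.30, 0.70) by default:

- days with **both** coordinates below their θ_lower quantiles become
  *missing* prototypes (the user neither engaged with nor carried the device);
- days with **both** coordinates above their θ_upper quantiles become
  *non-missing* prototypes;
- all other days stay unlabeled — mixed quadrants (high usage / low sensor
  activity, or vice versa) are genuinely ambiguous.

**Stage 2 — k-nearest-neighbor labeling.** Every unlabeled day receives the
majority label of its k nearest prototypes under Euclidean distance in the
feature space (default k = 5, validated so that k/2 never exceeds the size
of either prototype class; otherwise the vote is swamped by the majority
class). Prototype labels are never overwritten; days with no device record
at all are labeled `technical_missing`.

The package also provides the two comparison baselines (zero-removal and a
pooled one-class SVM trained on days of known non-missing status), a
synthetic panel generator with ground-truth use labels, sensitivity/
specificity grid experiments, MCAR/MAR masking, and a missForest-style
iterative random-forest imputer (within-user and across-users) evaluated by
NRMSE = sqrt(mean((X_obs − X_imp)²) / var(X_obs)).

## Worked example

```python
from twospamh import SimConfig, simulate_user, TwoSpamH, confusion_metrics

panel, truth = simulate_user(SimConfig(la=0.5, lu=0.5, T=100, seed=7))
res = TwoSpamH(panel).fit()          # thresholds (0.30, 0.70), k = 5
print(res.summary())
m = confusion_metrics(res.label_column("step_count").to_numpy(), truth.labels)
print(f"sensitivity = {m.sensitivity:.3f}  specificity = {m.specificity:.3f}")
```

prints

```
Two-stage device non-use labeling
=================================================
user:            sim_user
days (T):        100
thresholds:      (0.3, 0.7)
neighbors (k):   5

passive variable     protos miss  protos non  labeled miss tech miss
--------------------------------------------------------------------
step_count                    13          19            52         0
active_minutes                13          19            52         0

sensitivity = 1.000  specificity = 0.960
```

Stage 1 found 13 confident non-use days and 19 confident use days among the
100; after the KNN stage, 52 days are labeled missing in total. Against the
generator's ground truth, every true non-use day was flagged (sensitivity
1.000, with missing as the positive class) and 96% of true use days were
kept (specificity 0.960). The per-class prototype counts are the quantity to
monitor when tuning thresholds: fewer prototypes (e.g. thresholds 0.20/0.80)
raise sensitivity at the cost of specificity, and vice versa.

The same pipeline is available from the shell:

```sh
twospamh simulate --seed 1 --out panels.csv
twospamh label panels.csv --theta-lower 0.3 --theta-upper 0.7 -k 5 --out labels.csv
twospamh evaluate --reps 100 --methods zero,ocsvm,twospamh --out metrics.csv
```

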