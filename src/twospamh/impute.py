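"""Missing-data handling downstream of the labeling step.

Once a label matrix is available, the passive-measure cells deemed missing
are blanked and imputed.  The imputer is an iterative random-forest scheme in
the missForest style: start from mean imputation, then repeatedly regress
each passive variable on the others with a random forest and re-predict its
missing cells, stopping when the imputed values stop improving.  It runs
either *within-user* (one model per user) or *across-users* (all users
stacked into one model, with per-user mean covariates so the forest can
borrow each user's level).

For evaluating imputation quality, masking utilities blank observed cells
completely at random (MCAR) or conditionally on an observed driver variable
(MAR), and accuracy is measured by NRMSE — root mean squared error on the
masked cells normalized by the variance of their true values, so that plain
mean imputation scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.ensemble import RandomForestRegressor

from .panel import MISSING, TECHNICAL_MISSING, LabelMatrix

WITHIN_USER = "within_user"
ACROSS_USERS = "across_users"


@dataclass(frozen=True)
class MaskSpec:
    """How to blank observed cells for an imputation experiment.

    ``rate`` defaults to 0.225, the midpoint of the 20-25% band typically
    used for such evaluations.  MAR masking needs at least one fully
    observed driver column.
    """

    mechanism: str = "MCAR"
    rate: float = 0.225
    driver_cols: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be 'MCAR' or 'MAR'")
        if not 0.0 < self.rate < 1.0:
            raise ValueError("rate must lie strictly inside (0, 1)")


@dataclass
class ImputationResult:
    """Completed matrix plus bookkeeping from the iterative imputer."""

    X_imputed: pd.DataFrame
    mode: str
    iterations: int
    nrmse_per_variable: dict[str, float] = field(default_factory=dict)


def apply_missing_labels(x: pd.DataFrame, m: LabelMatrix) -> pd.DataFrame:
    """Blank the passive-measure cells labeled missing or technical-missing."""
    if x.shape != m.labels.shape or list(x.columns) != list(m.labels.columns):
        raise ValueError("X and label matrix shapes/columns do not match")
    out = x.copy()
    blank = m.labels.isin([MISSING, TECHNICAL_MISSING]).to_numpy()
    out.values[blank] = np.nan
    return out


def mask_mcar(x, spec: MaskSpec) -> np.ndarray:
    """Independent Bernoulli(rate) mask over the observed cells of ``x``."""
    arr = np.asarray(x, dtype=float)
    observed = ~np.isnan(arr)
    if not observed.any():
        raise ValueError("matrix has no observed cells to mask")
    rng = np.random.default_rng(spec.seed)
    return (rng.random(arr.shape) < spec.rate) & observed


def _standardized_driver(drivers: pd.DataFrame, cols: tuple[str, ...] | None) -> np.ndarray:
    use = drivers[list(cols)] if cols else drivers
    arr = use.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("MAR driver columns must be fully observed")
    sd = arr.std(axis=0, ddof=1)
    z = np.where(sd > 0, (arr - arr.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    combined = z.mean(axis=1)
    csd = combined.std(ddof=1)
    return combined / csd if csd > 0 else combined


def mask_mar(x, spec: MaskSpec, drivers: pd.DataFrame) -> np.ndarray:
    """Driver-dependent mask: P(masked) = expit(alpha_j + z_t) per column j.

    ``z_t`` is the standardized driver (mean of standardized driver columns);
    the intercept ``alpha_j`` is calibrated by root-finding so the expected
    masked fraction among the observed cells of column j equals
    ``spec.rate``.  A constant driver degenerates gracefully to MCAR.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if len(drivers) != arr.shape[0]:
        raise ValueError("drivers must align row-wise with x")
    z = _standardized_driver(drivers, spec.driver_cols)
    observed = ~np.isnan(arr)
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros(arr.shape, dtype=bool)
    for j in range(arr.shape[1]):
        rows = observed[:, j]
        if not rows.any():
            continue
        zj = z[rows]

        def marginal(alpha: float) -> float:
            return float(expit(alpha + zj).mean()) - spec.rate

        alpha = brentq(marginal, -60.0, 60.0, xtol=1e-6)
        p = expit(alpha + z)
        mask[:, j] = (rng.random(arr.shape[0]) < p) & rows
    return mask if np.asarray(x).ndim > 1 else mask[:, 0]


def nrmse(x_obs, x_imp) -> float:
    """Root mean squared error normalized by the population variance of truth.

    ``sqrt(mean((obs - imp)^2) / var_pop(obs))``; mean imputation scores
    exactly 1 under this convention.  Evaluated on held-out (masked) cells.
    """
    obs = np.asarray(x_obs, dtype=float)
    imp = np.asarray(x_imp, dtype=float)
    if obs.shape != imp.shape:
        raise ValueError("x_obs and x_imp must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 values")
    var = float(np.var(obs))  # population denominator n
    if var == 0.0:
        raise ValueError("zero variance in observed values; NRMSE undefined")
    return float(np.sqrt(np.mean((obs - imp) ** 2) / var))


def _missforest_matrix(
    x: pd.DataFrame, max_iter: int, n_trees: int, seed: int
) -> tuple[pd.DataFrame, int]:
    """Iterative RF imputation of one matrix; returns (completed, n_iters)."""
    arr = x.to_numpy(dtype=float)
    miss = np.isnan(arr)
    if arr.shape[1] < 2:
        raise ValueError("iterative imputation needs >= 2 variables")
    fully_missing = [c for c, m in zip(x.columns, miss.all(axis=0)) if m]
    if fully_missing:
        raise ValueError(f"variables {fully_missing} have no observed values")
    if not miss.any():
        return x.copy(), 0

    col_means = np.nanmean(arr, axis=0)
    cur = arr.copy()
    cur[miss] = np.take(col_means, np.nonzero(miss)[1])
    # Cycle variables from least to most missing, as missForest does.
    order = np.argsort(miss.sum(axis=0), kind="stable")
    order = [j for j in order if miss[:, j].any()]

    prev_delta = np.inf
    prev = cur.copy()
    n_done = 0
    for it in range(max_iter):
        new = cur.copy()
        for cycle_pos, j in enumerate(order):
            obs_rows = ~miss[:, j]
            other = [c for c in range(arr.shape[1]) if c != j]
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=(seed + 31 * it + cycle_pos) % (2**31),
                n_jobs=1,
            )
            rf.fit(new[obs_rows][:, other], arr[obs_rows, j])
            new[miss[:, j], j] = rf.predict(new[miss[:, j]][:, other])
        num = float(((new[miss] - cur[miss]) ** 2).sum())
        den = float((new[miss] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        n_done = it + 1
        if delta > prev_delta:
            # The update stopped improving: keep the previous iterate.
            return pd.DataFrame(prev, index=x.index, columns=x.columns), n_done
        prev, cur, prev_delta = cur, new, delta
    return pd.DataFrame(cur, index=x.index, columns=x.columns), n_done


def impute_rf(
    x: pd.DataFrame | dict[str, pd.DataFrame],
    mode: str = WITHIN_USER,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> ImputationResult | dict[str, ImputationResult]:
    """missForest-style imputation of passive-measure matrices.

    ``x`` is either a single user's matrix, or a dict of per-user matrices.
    ``within_user`` fits a separate model per matrix; ``across_users`` stacks
    all users into one model, adding each user's per-variable observed means
    as covariates so the forest can learn shared structure without losing
    user levels.  Observed cells are never altered.
    """
    if mode not in (WITHIN_USER, ACROSS_USERS):
        raise ValueError(f"mode must be {WITHIN_USER!r} or {ACROSS_USERS!r}")
    if isinstance(x, pd.DataFrame):
        completed, iters = _missforest_matrix(x, max_iter, n_trees, seed)
        return ImputationResult(X_imputed=completed, mode=mode, iterations=iters)
    if mode == WITHIN_USER:
        out: dict[str, ImputationResult] = {}
        for i, (uid, xu) in enumerate(sorted(x.items())):
            completed, iters = _missforest_matrix(xu, max_iter, n_trees, seed + i)
            out[uid] = ImputationResult(X_imputed=completed, mode=mode,
                                        iterations=iters)
        return out
    # across_users: stack, with per-user mean covariates.
    users = sorted(x.items())
    cols = list(users[0][1].columns)
    blocks = []
    for uid, xu in users:
        if list(xu.columns) != cols:
            raise ValueError("all users must share the same passive variables")
        block = xu.copy()
        for c in cols:
            block[f"_user_mean_{c}"] = float(np.nanmean(xu[c].to_numpy(float)))
        blocks.append(block)
    stacked = pd.concat(blocks, keys=[uid for uid, _ in users], names=["user_id"])
    completed, iters = _missforest_matrix(stacked, max_iter, n_trees, seed)
    out: dict[str, ImputationResult] = {}
    for uid, _ in users:
        out[uid] = ImputationResult(
            X_imputed=completed.loc[uid][cols], mode=mode, iterations=iters
        )
    return out


def evaluate_imputation(
    xs: dict[str, pd.DataFrame],
    labels: dict[str, LabelMatrix],
    spec: MaskSpec,
    modes: tuple[str, ...] = (WITHIN_USER, ACROSS_USERS),
    drivers: dict[str, pd.DataFrame] | None = None,
    max_iter: int = 10,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Mask-and-impute evaluation protocol on labeled panels.

    Cells the labeling step deemed non-missing are taken as ground truth;
    cells deemed missing (or technically missing) are dropped.  Observed
    cells are then masked per ``spec``, imputed per mode, and compared to the
    held-out truth.  Returns a tidy table with columns
    ``variable, method, mechanism, nrmse``.
    """
    truths: dict[str, pd.DataFrame] = {}
    masked: dict[str, pd.DataFrame] = {}
    masks: dict[str, np.ndarray] = {}
    for i, (uid, xu) in enumerate(sorted(xs.items())):
        ground = apply_missing_labels(xu, labels[uid])
        sub = MaskSpec(
            mechanism=spec.mechanism, rate=spec.rate,
            driver_cols=spec.driver_cols, seed=spec.seed + i,
        )
        if spec.mechanism == "MCAR":
            m = mask_mcar(ground, sub)
        else:
            if drivers is None:
                raise ValueError("MAR masking requires driver frames")
            m = mask_mar(ground, sub, drivers[uid])
        xm = ground.copy()
        xm.values[m] = np.nan
        truths[uid], masked[uid], masks[uid] = ground, xm, m

    rows = []
    for mode in modes:
        results = impute_rf(masked, mode=mode, max_iter=max_iter,
                            n_trees=n_trees, seed=spec.seed)
        method = f"missforest_{mode}"
        for j, var in enumerate(next(iter(xs.values())).columns):
            obs_all, imp_all = [], []
            for uid in sorted(xs):
                m = masks[uid][:, j]
                obs_all.append(truths[uid].to_numpy(float)[m, j])
                imp_all.append(results[uid].X_imputed.to_numpy(float)[m, j])
            obs = np.concatenate(obs_all)
            imp = np.concatenate(imp_all)
            rows.append({
                "variable": var,
                "method": method,
                "mechanism": spec.mechanism,
                "nrmse": nrmse(obs, imp) if obs.size >= 2 and np.var(obs) > 0
                else float("nan"),
                "n_masked": int(obs.size),
            })
    return pd.DataFrame(rows)
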