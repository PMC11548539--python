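"""Sensitivity/specificity evaluation and the simulation grid experiment.

The positive class is *missing*: sensitivity is the proportion of
truth-missing days that a method labels missing, specificity the proportion
of truth-non-missing days labeled non-missing.  High sensitivity matters most
here — it is what keeps unreliable device-non-use days out of downstream
analyses.

The grid experiment simulates one user per (activity level, usage level)
cell, runs the requested methods on identical panels, and pools the confusion
counts over replicates before forming the ratios (robust when a single
replicate has few truth-missing days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import OcsvmParams, ocsvm_labels, sample_train_rows, zero_removal
from .model import InvalidKError, PrototypeError, Thresholds, TwoSpamH
from .panel import MISSING, NON_MISSING, TECHNICAL_MISSING
from .simulate import DEFAULT_GRID, SimConfig, SimParams, simulate_user

METHODS = ("zero", "ocsvm", "twospamh")


@dataclass
class ConfusionCounts:
    """Pooled confusion counts with missing as the positive class."""

    tp: int = 0  # predicted missing, truth missing
    fn: int = 0  # predicted non-missing, truth missing
    tn: int = 0  # predicted non-missing, truth non-missing
    fp: int = 0  # predicted missing, truth non-missing
    n_failed: int = 0  # replicates where the method could not run

    def add(self, other: "ConfusionCounts") -> None:
        self.tp += other.tp
        self.fn += other.fn
        self.tn += other.tn
        self.fp += other.fp
        self.n_failed += other.n_failed

    @property
    def sensitivity(self) -> float | None:
        n = self.tp + self.fn
        return self.tp / n if n else None

    @property
    def specificity(self) -> float | None:
        n = self.tn + self.fp
        return self.tn / n if n else None


@dataclass
class EvalMetrics:
    """Sensitivity/specificity for one method (optionally one grid cell)."""

    sensitivity: float | None
    specificity: float | None
    n_missing_truth: int
    n_nonmissing_truth: int
    method: str = ""
    cell: tuple[float, float] | None = None


def count_confusion(predicted, truth_labels) -> ConfusionCounts:
    """Confusion counts of a predicted label column against the truth.

    Days the method marked technical-missing are excluded (no prediction was
    made for them).
    """
    pred = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth_labels, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("predicted and truth labels must have equal length")
    keep = pred != TECHNICAL_MISSING
    pred, truth = pred[keep], truth[keep]
    return ConfusionCounts(
        tp=int(((pred == MISSING) & (truth == MISSING)).sum()),
        fn=int(((pred == NON_MISSING) & (truth == MISSING)).sum()),
        tn=int(((pred == NON_MISSING) & (truth == NON_MISSING)).sum()),
        fp=int(((pred == MISSING) & (truth == NON_MISSING)).sum()),
    )


def confusion_metrics(predicted, truth_labels, method: str = "",
                      cell: tuple[float, float] | None = None) -> EvalMetrics:
    """Sensitivity and specificity of predicted labels against the truth.

    A metric whose truth class is empty is reported as ``None`` (undefined),
    never as 0.
    """
    c = count_confusion(predicted, truth_labels)
    return EvalMetrics(
        sensitivity=c.sensitivity,
        specificity=c.specificity,
        n_missing_truth=c.tp + c.fn,
        n_nonmissing_truth=c.tn + c.fp,
        method=method,
        cell=cell,
    )


def grid_experiment(
    la_values=DEFAULT_GRID,
    lu_values=DEFAULT_GRID,
    T: int = 100,
    reps: int = 100,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    thresholds: Thresholds = Thresholds(),
    k: int = 5,
    ocsvm_params: OcsvmParams = OcsvmParams(),
    sim_params: SimParams | None = None,
    passive_col: str = "step_count",
) -> pd.DataFrame:
    """Run the simulation study grid and return a tidy metrics table.

    One user per cell, ``reps`` replicate panels each.  All methods see the
    same panels.  The one-class SVM is trained once per replicate on a pooled
    sample of truth-non-missing user-days across the whole grid and evaluated
    on the remaining days; the two-stage algorithm and zero-removal run per
    user.  Replicates where the two-stage algorithm cannot run (empty
    prototype class or invalid k) are skipped for that method and counted in
    ``n_failed``.

    Returns a DataFrame with columns
    ``L_A, L_U, method, sensitivity, specificity, n_missing_truth,
    n_nonmissing_truth, n_failed``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    sim_params = sim_params or SimParams()
    cells = [(i, float(la), j, float(lu))
             for i, la in enumerate(la_values) for j, lu in enumerate(lu_values)]
    counts: dict[tuple[float, float, str], ConfusionCounts] = {
        (la, lu, m): ConfusionCounts() for _, la, _, lu in cells for m in methods
    }

    for rep in range(reps):
        panels = []
        for i, la, j, lu in cells:
            ss = np.random.SeedSequence([int(seed), i, j, rep])
            cfg = SimConfig(la=la, lu=lu, T=T, seed=ss,
                            user_id=f"u_la{la:g}_lu{lu:g}", params=sim_params)
            panel, truth = simulate_user(cfg)
            panels.append((la, lu, panel, truth))

        if "zero" in methods:
            for la, lu, panel, truth in panels:
                pred = zero_removal(panel.X[passive_col])
                counts[(la, lu, "zero")].add(count_confusion(pred, truth.labels))

        if "twospamh" in methods:
            for la, lu, panel, truth in panels:
                try:
                    res = TwoSpamH(
                        panel, passive_cols=[passive_col],
                        thresholds=thresholds, k=k,
                    ).fit()
                except (PrototypeError, InvalidKError):
                    counts[(la, lu, "twospamh")].n_failed += 1
                    continue
                pred = res.label_column(passive_col).to_numpy()
                counts[(la, lu, "twospamh")].add(count_confusion(pred, truth.labels))

        if "ocsvm" in methods:
            feats = np.vstack([
                np.column_stack([p.W.to_numpy(float), p.Z.to_numpy(float)])
                for _, _, p, _ in panels
            ])
            truth_all = np.concatenate([t.labels for _, _, _, t in panels])
            cell_of_row = np.concatenate([
                np.full(p.T, ci) for ci, (_, _, p, _) in enumerate(panels)
            ])
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9999, rep]))
            train_idx = sample_train_rows(truth_all, ocsvm_params.train_size, rng)
            pred_all = ocsvm_labels(feats, train_idx, ocsvm_params)
            eval_mask = np.ones(len(pred_all), dtype=bool)
            eval_mask[train_idx] = False
            for ci, (la, lu, _, _) in enumerate(panels):
                m = eval_mask & (cell_of_row == ci)
                counts[(la, lu, "ocsvm")].add(
                    count_confusion(pred_all[m], truth_all[m])
                )

    rows = []
    for (_, la, _, lu) in cells:
        for m in methods:
            c = counts[(la, lu, m)]
            rows.append({
                "L_A": la, "L_U": lu, "method": m,
                "sensitivity": c.sensitivity, "specificity": c.specificity,
                "n_missing_truth": c.tp + c.fn,
                "n_nonmissing_truth": c.tn + c.fp,
                "n_failed": c.n_failed,
            })
    return pd.DataFrame(rows)


def plot_heatmaps(table: pd.DataFrame, out_prefix: str) -> list[str]:
    """Write one sensitivity and one specificity heatmap per method.

    Layout mirrors the grid experiment: rows are activity levels, columns
    usage levels.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for metric in ("sensitivity", "specificity"):
        methods = list(dict.fromkeys(table["method"]))
        fig, axes = plt.subplots(1, len(methods), figsize=(4 * len(methods), 3.4),
                                 squeeze=False)
        for ax, m in zip(axes[0], methods):
            piv = table[table["method"] == m].pivot(
                index="L_A", columns="L_U", values=metric
            ).sort_index(ascending=False)
            im = ax.imshow(piv.to_numpy(float), vmin=0, vmax=1, cmap="viridis",
                           aspect="auto")
            ax.set_xticks(range(piv.shape[1]), [f"{v:g}" for v in piv.columns])
            ax.set_yticks(range(piv.shape[0]), [f"{v:g}" for v in piv.index])
            ax.set_xlabel("usage level $L_U$")
            ax.set_ylabel("activity level $L_A$")
            ax.set_title(f"{m}: {metric}")
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = f"{out_prefix}_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
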