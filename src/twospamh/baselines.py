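"""Comparison methods: zero-removal and a one-class SVM novelty detector.

Zero-removal mimics the common ad-hoc practice of declaring a day missing
whenever the recorded passive value is zero — a single cutoff shared by all
users.  The one-class SVM is a semi-supervised reference point: it is trained
on a pooled sample of days *known* to be non-missing (information unavailable
in real deployments) and flags days outside the learned boundary as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .panel import MISSING, NON_MISSING, TECHNICAL_MISSING


@dataclass(frozen=True)
class OcsvmParams:
    """RBF one-class SVM settings; gamma='scale' is 1/(n_features * var)."""

    nu: float = 0.10
    gamma: str | float = "scale"
    train_size: int = 300

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must lie in (0, 1]")
        if self.train_size < 10:
            raise ValueError("train_size must be >= 10")


def zero_removal(x) -> pd.Series:
    """Label days with a zero passive value as missing, positives non-missing.

    Technical-missing (NaN) cells pass through; negative values are invalid
    for count-like passive measures and raise.
    """
    s = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    if (s.dropna() < 0).any():
        raise ValueError("zero-removal expects non-negative passive values")
    out = pd.Series(NON_MISSING, index=s.index, dtype=object)
    out[s == 0] = MISSING
    out[s.isna()] = TECHNICAL_MISSING
    return out


def ocsvm_labels(
    features: np.ndarray,
    train_idx: np.ndarray,
    params: OcsvmParams = OcsvmParams(),
) -> np.ndarray:
    """One-class SVM labels for all rows, trained on known non-missing rows.

    ``features`` stacks the sensor-activity and device-usage variables (W
    alongside Z) for every pooled user-day; ``train_idx`` indexes rows of
    known non-missing status.  Features are standardized with statistics
    fitted on the training rows only.  Rows inside the learned boundary are
    labeled non-missing, rows outside missing (training rows included, for a
    label on every day).
    """
    features = np.asarray(features, dtype=float)
    train_idx = np.asarray(train_idx)
    if len(train_idx) < params.train_size and len(train_idx) < 10:
        raise ValueError("too few known non-missing rows to train on")
    train = features[train_idx]
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    svm = OneClassSVM(kernel="rbf", nu=params.nu, gamma=params.gamma)
    svm.fit((train - mu) / sd)
    pred = svm.predict((features - mu) / sd)
    return np.where(pred == 1, NON_MISSING, MISSING).astype(object)


def sample_train_rows(
    truth_labels: np.ndarray, train_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample row indices with true non-missing status for SVM training."""
    candidates = np.flatnonzero(np.asarray(truth_labels, dtype=object) == NON_MISSING)
    if len(candidates) < train_size:
        raise ValueError(
            f"only {len(candidates)} non-missing rows available; "
            f"cannot sample {train_size}"
        )
    return rng.choice(candidates, size=train_size, replace=False)
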