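"""2-D feature space of device usage vs sensor activity.

Each usable day t is mapped to a point f_t = (c_t^Z, c_t^W), where c^Z is the
first principal component of the device-usage block Z and c^W the first
principal component of the sensor-activity block W (a single column passes
through directly).  PCA is done on the correlation scale — columns are
standardized first — because usage variables live on wildly different scales
(counts vs battery variance).  Both resulting axes are re-standardized to unit
sample variance so that the Euclidean distances used downstream weigh the two
axes equally, and each axis is sign-oriented so that larger coordinates mean
*more* device use / sensor activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import DailyPanel, MIN_DAYS


class DegenerateInputError(ValueError):
    """Raised when a block has no variation (or too few rows) to embed."""


def standardize_columns(m: np.ndarray) -> np.ndarray:
    """Center each column and scale it to unit sample standard deviation.

    Zero-spread columns map to all-zeros rather than dividing by zero.
    Requires at least 2 rows.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.shape[0] < 2:
        raise DegenerateInputError("standardization needs >= 2 rows")
    centered = m - m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    # a bit-identical constant column can still give a tiny nonzero sd
    # through summation rounding; require actual spread before dividing
    nz = (sd > 0) & (m.max(axis=0) > m.min(axis=0))
    out = np.zeros_like(centered)
    out[:, nz] = centered[:, nz] / sd[nz]
    return out


def _orient(scores: np.ndarray, std_m: np.ndarray) -> tuple[np.ndarray, int]:
    """Fix the PC sign so scores track overall usage upward (ties: +1)."""
    rowsum = std_m.sum(axis=1)
    cov = float(np.dot(scores - scores.mean(), rowsum - rowsum.mean()))
    sign = -1 if cov < 0 else 1
    return sign * scores, sign


def first_principal_component(m: np.ndarray) -> tuple[np.ndarray, int]:
    """First-principal-component scores of a column-standardized matrix.

    Returns ``(scores, sign)`` where ``sign`` is the orientation factor
    applied so that the scores correlate non-negatively with the row-wise sum
    of the standardized columns.  A single-column matrix passes through as its
    standardized self.  All-constant input is degenerate and raises.
    """
    std_m = standardize_columns(m)
    if not (std_m.std(axis=0) > 0).any():
        raise DegenerateInputError("all columns are constant; no principal component")
    if std_m.shape[1] == 1:
        scores = std_m[:, 0].copy()
    else:
        # SVD of the centered/standardized matrix: scores = U1 * s1.
        u, s, _ = np.linalg.svd(std_m, full_matrices=False)
        scores = u[:, 0] * s[0]
    return _orient(scores, std_m)


@dataclass
class FeatureSpace:
    """Per-day points (c^Z, c^W) for the days with fully observed W and Z.

    ``points`` is an (n, 2) array; ``included_rows`` maps each point back to
    its positional row in the source panel.
    """

    points: np.ndarray
    included_rows: np.ndarray
    days: pd.DatetimeIndex
    orientation_sign_z: int
    orientation_sign_w: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def c_z(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def c_w(self) -> np.ndarray:
        return self.points[:, 1]


def build_feature_space(
    p: DailyPanel, w_cols: list[str] | None = None, z_cols: list[str] | None = None
) -> FeatureSpace:
    """Construct the feature space F from a panel's W and Z blocks.

    Rows with a technical-missing (NaN) value in any used W or Z column are
    excluded first; at least :data:`~twospamh.panel.MIN_DAYS` rows must
    remain.  ``w_cols``/``z_cols`` restrict the blocks (per-passive-variable
    sensor mapping); default is all columns.
    """
    W = p.W[w_cols] if w_cols is not None else p.W
    Z = p.Z[z_cols] if z_cols is not None else p.Z
    mask = ~(W.isna().any(axis=1) | Z.isna().any(axis=1))
    included = np.flatnonzero(mask.to_numpy())
    if len(included) < MIN_DAYS:
        raise DegenerateInputError(
            f"only {len(included)} fully observed days; need >= {MIN_DAYS}"
        )
    z_scores, sign_z = first_principal_component(Z.to_numpy(dtype=float)[included])
    w_scores, sign_w = first_principal_component(W.to_numpy(dtype=float)[included])
    # Unit-variance axes: keep Euclidean distance from being dominated by the
    # axis whose PC happens to carry more variance.
    c_z = standardize_columns(z_scores)[:, 0]
    c_w = standardize_columns(w_scores)[:, 0]
    return FeatureSpace(
        points=np.column_stack([c_z, c_w]),
        included_rows=included,
        days=p.days[included],
        orientation_sign_z=sign_z,
        orientation_sign_w=sign_w,
    )
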