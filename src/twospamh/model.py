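"""Two-stage inference of device non-use labels for one user's panel.

Stage 1 converts the unsupervised problem into a semi-supervised one: days
falling in the lower-left quadrant of the (device-usage, sensor-activity)
feature space — both coordinates below the lower quantile threshold — are
taken as *missing* prototypes (the user neither engaged with nor carried the
device), and days in the upper-right quadrant — both coordinates above the
upper threshold — as *non-missing* prototypes.  Stage 2 labels every
remaining day by a k-nearest-neighbors majority vote among the prototypes
under Euclidean distance.  Prototype labels are never overwritten.

The public surface follows the model/results convention: build a
:class:`TwoSpamH` model from a panel, call :meth:`~TwoSpamH.fit`, and read
labels and diagnostics off the returned :class:`TwoSpamHResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSpace, build_feature_space
from .panel import (
    MISSING,
    NON_MISSING,
    TECHNICAL_MISSING,
    UNLABELED,
    DailyPanel,
    LabelMatrix,
    validate_panel,
)


class PrototypeError(ValueError):
    """Raised when stage 1 yields an empty prototype class.

    The practical remedy is to widen the prototype band (lower
    ``theta_lower`` and/or raise ``theta_upper``) until both classes are
    populated; the thresholds should be chosen by monitoring the number of
    prototypes selected per class.
    """


class InvalidKError(ValueError):
    """Raised when the neighborhood size fails the class-balance rule."""


@dataclass(frozen=True)
class Thresholds:
    """Quantile thresholds bounding the prototype quadrants.

    Defaults (0.30, 0.70): days below the 30th percentile on both axes are
    missing prototypes, days above the 70th on both axes non-missing ones.
    """

    theta_lower: float = 0.30
    theta_upper: float = 0.70

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_lower < 1.0 and 0.0 < self.theta_upper < 1.0):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if not self.theta_lower < self.theta_upper:
            raise ValueError("theta_lower must be < theta_upper")


@dataclass
class PrototypeSet:
    """Stage-1 partition of feature-space point indices."""

    missing_idx: np.ndarray
    non_missing_idx: np.ndarray
    unlabeled_idx: np.ndarray

    @property
    def n_missing(self) -> int:
        return len(self.missing_idx)

    @property
    def n_non_missing(self) -> int:
        return len(self.non_missing_idx)


@dataclass(frozen=True)
class KValidation:
    """Outcome of the neighborhood-size validity check."""

    ok: bool
    k: int
    half_k: float
    n_missing: int
    n_non_missing: int
    reason: str | None = None


def empirical_quantile(v: np.ndarray, theta: float) -> float:
    """Linear-interpolation empirical quantile of a finite vector.

    With sorted values v(1..n) and h = (n-1)*theta + 1, returns
    v(floor(h)) + (h - floor(h)) * (v(floor(h)+1) - v(floor(h))).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("quantile of an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("quantile requires finite values")
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta={theta} outside [0, 1]")
    # numpy's default 'linear' method is exactly this interpolation rule.
    return float(np.quantile(v, theta))


def select_prototypes(f: FeatureSpace, th: Thresholds = Thresholds()) -> PrototypeSet:
    """Stage 1: label extreme-quadrant points as prototypes.

    Strict inequalities throughout; points tied with a quantile stay
    unlabeled.  Both classes may come out empty here — the caller decides
    whether that is fatal.
    """
    q_low_z = empirical_quantile(f.c_z, th.theta_lower)
    q_up_z = empirical_quantile(f.c_z, th.theta_upper)
    q_low_w = empirical_quantile(f.c_w, th.theta_lower)
    q_up_w = empirical_quantile(f.c_w, th.theta_upper)
    miss = (f.c_z < q_low_z) & (f.c_w < q_low_w)
    non = (f.c_z > q_up_z) & (f.c_w > q_up_w)
    return PrototypeSet(
        missing_idx=np.flatnonzero(miss),
        non_missing_idx=np.flatnonzero(non),
        unlabeled_idx=np.flatnonzero(~miss & ~non),
    )


def validate_k(k: int, proto: PrototypeSet) -> KValidation:
    """Check the class-balance rule for the neighborhood size.

    ``k`` is acceptable when 1 <= k <= (total prototypes) and the
    half-neighborhood k/2 does not exceed the size of either prototype
    class; otherwise every vote would be swamped by the majority class.
    """
    n_m, n_n = proto.n_missing, proto.n_non_missing
    half = k / 2
    if k < 1:
        reason = f"k={k} must be a positive integer"
    elif k > n_m + n_n:
        reason = f"k={k} exceeds the total number of prototypes ({n_m + n_n})"
    elif half > min(n_m, n_n):
        small = MISSING if n_m <= n_n else NON_MISSING
        reason = (
            f"half-neighborhood k/2 = {half:g} exceeds the number of "
            f"{small!r} prototypes (min class size {min(n_m, n_n)})"
        )
    else:
        reason = None
    return KValidation(
        ok=reason is None, k=k, half_k=half, n_missing=n_m, n_non_missing=n_n,
        reason=reason,
    )


def knn_classify(f: FeatureSpace, proto: PrototypeSet, k: int) -> np.ndarray:
    """Stage 2: majority vote of the k nearest prototypes per unlabeled point.

    Deterministic tie-breaking: a split vote goes to the label of the single
    nearest prototype; if both labels are present at exactly the nearest
    distance, to ``missing``.  Distance ties at the k-th neighbor are broken
    by lower prototype point index.

    Returns an array of labels aligned with ``proto.unlabeled_idx``.
    """
    check = validate_k(k, proto)
    if not check.ok:
        raise InvalidKError(check.reason)
    if proto.n_missing == 0 or proto.n_non_missing == 0:
        raise PrototypeError("both prototype classes must be non-empty for KNN")
    proto_idx = np.concatenate([proto.missing_idx, proto.non_missing_idx])
    proto_lab = np.array(
        [MISSING] * proto.n_missing + [NON_MISSING] * proto.n_non_missing, dtype=object
    )
    # Sort prototypes by point index so that lexsort on (distance, position)
    # realizes the lower-point-index tie rule.
    order = np.argsort(proto_idx, kind="stable")
    proto_idx, proto_lab = proto_idx[order], proto_lab[order]
    proto_pts = f.points[proto_idx]

    out = np.empty(len(proto.unlabeled_idx), dtype=object)
    for j, t in enumerate(proto.unlabeled_idx):
        d = np.sqrt(((proto_pts - f.points[t]) ** 2).sum(axis=1))
        nearest = np.lexsort((np.arange(len(d)), d))[:k]
        votes_missing = int((proto_lab[nearest] == MISSING).sum())
        if votes_missing * 2 > k:
            out[j] = MISSING
        elif votes_missing * 2 < k:
            out[j] = NON_MISSING
        else:
            d_min = d[nearest[0]]
            at_min = proto_lab[nearest][d[nearest] == d_min]
            if (at_min == MISSING).any() and (at_min == NON_MISSING).any():
                out[j] = MISSING
            else:
                out[j] = at_min[0]
    return out


@dataclass
class TwoSpamHResults:
    """Fitted labels and stage diagnostics for one user.

    Attributes
    ----------
    labels : LabelMatrix over all T days and all requested passive columns;
        technical-missing days carry ``technical_missing``, every other day
        carries ``missing`` or ``non_missing``.
    feature_spaces, prototypes, k_checks : per-passive-column diagnostics.
    """

    model: "TwoSpamH"
    labels: LabelMatrix
    feature_spaces: dict[str, FeatureSpace]
    prototypes: dict[str, PrototypeSet]
    k_checks: dict[str, KValidation]

    def label_column(self, passive_col: str) -> pd.Series:
        return self.labels.labels[passive_col]

    def prototype_counts(self) -> pd.DataFrame:
        """Per-column prototype class sizes — the quantity to monitor when
        choosing thresholds."""
        rows = {
            c: {
                "n_missing_prototypes": p.n_missing,
                "n_non_missing_prototypes": p.n_non_missing,
                "n_unlabeled": len(p.unlabeled_idx),
            }
            for c, p in self.prototypes.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Two-stage device non-use labeling",
            "=" * 49,
            f"user:            {m.panel.user_id}",
            f"days (T):        {m.panel.T}",
            f"thresholds:      ({m.thresholds.theta_lower:g}, {m.thresholds.theta_upper:g})",
            f"neighbors (k):   {m.k}",
            "",
            f"{'passive variable':<20}{'protos miss':>12}{'protos non':>12}"
            f"{'labeled miss':>14}{'tech miss':>10}",
            "-" * 68,
        ]
        for c in self.labels.labels.columns:
            lab = self.labels.labels[c]
            p = self.prototypes[c]
            lines.append(
                f"{c:<20}{p.n_missing:>12d}{p.n_non_missing:>12d}"
                f"{int((lab == MISSING).sum()):>14d}"
                f"{int((lab == TECHNICAL_MISSING).sum()):>10d}"
            )
        return "\n".join(lines)


class TwoSpamH:
    """Two-stage non-use labeling model for one user's daily panel.

    Parameters
    ----------
    panel : the user's :class:`~twospamh.panel.DailyPanel`.
    passive_cols : passive columns of ``X`` to label (default: all).
    thresholds : stage-1 quantile thresholds.
    k : stage-2 neighborhood size (validated against the prototype counts).
    w_cols_map, z_cols_map : optional per-passive-column restriction of the
        sensor-activity / device-usage blocks; by default one shared feature
        space serves every passive column.
    """

    def __init__(
        self,
        panel: DailyPanel,
        passive_cols: list[str] | None = None,
        thresholds: Thresholds = Thresholds(),
        k: int = 5,
        w_cols_map: dict[str, list[str]] | None = None,
        z_cols_map: dict[str, list[str]] | None = None,
    ) -> None:
        fatal = [i for i in validate_panel(panel) if i.fatal]
        if fatal:
            raise ValueError(
                "panel fails validation: " + "; ".join(i.message for i in fatal)
            )
        self.panel = panel
        self.passive_cols = list(passive_cols) if passive_cols else panel.x_cols
        self.thresholds = thresholds
        self.k = int(k)
        self.w_cols_map = w_cols_map or {}
        self.z_cols_map = z_cols_map or {}

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_cols: list[str],
        w_cols: list[str],
        z_cols: list[str],
        date_col: str = "date",
        user_id: str = "user",
        **kwargs,
    ) -> "TwoSpamH":
        """Build the model straight from a tidy per-day DataFrame."""
        idx = pd.DatetimeIndex(pd.to_datetime(df[date_col]))
        order = np.argsort(idx.values, kind="stable")
        panel = DailyPanel(
            user_id=user_id,
            X=df[x_cols].astype(float).iloc[order].set_axis(idx[order]),
            W=df[w_cols].astype(float).iloc[order].set_axis(idx[order]),
            Z=df[z_cols].astype(float).iloc[order].set_axis(idx[order]),
        )
        return cls(panel, **kwargs)

    def _fit_column(self, col: str) -> tuple[pd.Series, FeatureSpace, PrototypeSet, KValidation]:
        panel = self.panel
        f = build_feature_space(
            panel, self.w_cols_map.get(col), self.z_cols_map.get(col)
        )
        proto = select_prototypes(f, self.thresholds)
        if proto.n_missing == 0 or proto.n_non_missing == 0:
            empty = MISSING if proto.n_missing == 0 else NON_MISSING
            raise PrototypeError(
                f"column {col!r}: no {empty!r} prototypes at thresholds "
                f"({self.thresholds.theta_lower:g}, {self.thresholds.theta_upper:g}); "
                "widen the prototype band (lower theta_lower and/or raise "
                "theta_upper) and monitor the per-class prototype counts"
            )
        check = validate_k(self.k, proto)
        if not check.ok:
            raise InvalidKError(f"column {col!r}: {check.reason}")

        point_labels = np.full(f.n_points, UNLABELED, dtype=object)
        point_labels[proto.missing_idx] = MISSING
        point_labels[proto.non_missing_idx] = NON_MISSING
        point_labels[proto.unlabeled_idx] = knn_classify(f, proto, self.k)

        labels = pd.Series(TECHNICAL_MISSING, index=panel.days, dtype=object, name=col)
        labels.iloc[f.included_rows] = point_labels
        # A day whose passive cell itself is absent is technical-missing for
        # that column regardless of the device proxies.
        labels[panel.X[col].isna().to_numpy()] = TECHNICAL_MISSING
        return labels, f, proto, check

    def fit(self) -> TwoSpamHResults:
        """Run both stages for every requested passive column."""
        cols, spaces, protos, checks = {}, {}, {}, {}
        for col in self.passive_cols:
            labels, f, proto, check = self._fit_column(col)
            cols[col] = labels
            spaces[col], protos[col], checks[col] = f, proto, check
        lm = LabelMatrix(
            user_id=self.panel.user_id,
            labels=pd.DataFrame(cols, index=self.panel.days)[self.passive_cols],
        )
        return TwoSpamHResults(
            model=self, labels=lm, feature_spaces=spaces, prototypes=protos,
            k_checks=checks,
        )


def run_2spamh(
    p: DailyPanel,
    passive_col: str,
    th: Thresholds = Thresholds(),
    k: int = 5,
    w_cols: list[str] | None = None,
    z_cols: list[str] | None = None,
) -> pd.Series:
    """Label one passive column of a panel; returns a day-indexed Series."""
    model = TwoSpamH(
        p,
        passive_cols=[passive_col],
        thresholds=th,
        k=k,
        w_cols_map={passive_col: w_cols} if w_cols else None,
        z_cols_map={passive_col: z_cols} if z_cols else None,
    )
    return model.fit().label_column(passive_col)


def run_2spamh_all(
    p: DailyPanel,
    th: Thresholds = Thresholds(),
    k: int = 5,
    w_cols_map: dict[str, list[str]] | None = None,
    z_cols_map: dict[str, list[str]] | None = None,
) -> LabelMatrix:
    """Label every passive column of a panel; returns the full matrix M."""
    model = TwoSpamH(p, thresholds=th, k=k, w_cols_map=w_cols_map, z_cols_map=z_cols_map)
    return model.fit().labels
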