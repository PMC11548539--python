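"""Per-user daily panels of passively sensed data, and their label matrices.

A panel holds three blocks of day-indexed variables for one user:

* ``X`` — passive measures (e.g. daily step count), the quantities whose
  reliability is in question;
* ``W`` — sensor-activity variables (e.g. daily number of uploads to the
  server), a proxy for the sensor actually recording data;
* ``Z`` — device-usage variables (e.g. screen unlocks, battery variance,
  notifications), a proxy for the user engaging with the device.

Cells that are absent in the raw CSV (the device produced no record at all)
are *technical missing* and are represented as NaN in memory — they are never
coerced to 0, since a recorded zero (no steps taken) and an absent record
(device off) mean different things.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Label vocabulary for the missing-label matrix M.
MISSING = "missing"
NON_MISSING = "non_missing"
UNLABELED = "unlabeled"
TECHNICAL_MISSING = "technical_missing"

LABELS = (MISSING, NON_MISSING, UNLABELED, TECHNICAL_MISSING)

#: Minimum number of usable days for the two-stage algorithm. Below this,
#: 30/70% quantile thresholds cannot reliably yield prototypes in both
#: classes.
MIN_DAYS = 10


class PanelError(ValueError):
    """Raised for malformed panel input (duplicate dates, bad schema, ...)."""


@dataclass(frozen=True)
class PanelSchema:
    """Column-role mapping for reading panel CSVs.

    Parameters
    ----------
    date : name of the date column (ISO-8601 dates).
    x, w, z : column names playing the passive-measure, sensor-activity and
        device-usage roles respectively.
    user_id : optional name of a user-id column (long-format multi-user CSV).
    """

    date: str = "date"
    x: tuple[str, ...] = ()
    w: tuple[str, ...] = ()
    z: tuple[str, ...] = ()
    user_id: str | None = None

    def __post_init__(self) -> None:
        for role, cols in (("x", self.x), ("w", self.w), ("z", self.z)):
            if len(cols) == 0:
                raise PanelError(f"schema maps no column to required role {role!r}")
        object.__setattr__(self, "x", tuple(self.x))
        object.__setattr__(self, "w", tuple(self.w))
        object.__setattr__(self, "z", tuple(self.z))


@dataclass
class DailyPanel:
    """One user's day-indexed table of passive measures and device proxies.

    ``X``, ``W``, ``Z`` are float DataFrames sharing a strictly increasing
    ``DatetimeIndex`` of T days; NaN marks technical-missing cells.
    """

    user_id: str
    X: pd.DataFrame
    W: pd.DataFrame
    Z: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.X.index
        if not (self.W.index.equals(idx) and self.Z.index.equals(idx)):
            raise PanelError("X, W, Z must share the same day index")
        if idx.has_duplicates:
            raise PanelError(f"duplicate dates in panel for user {self.user_id!r}")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise PanelError("panel days must be strictly increasing")

    @property
    def days(self) -> pd.DatetimeIndex:
        return self.X.index

    @property
    def T(self) -> int:
        return len(self.X.index)

    @property
    def x_cols(self) -> list[str]:
        return list(self.X.columns)

    @property
    def w_cols(self) -> list[str]:
        return list(self.W.columns)

    @property
    def z_cols(self) -> list[str]:
        return list(self.Z.columns)


@dataclass
class LabelMatrix:
    """Missing-label matrix M: one label per (day, passive variable).

    ``labels`` is a DataFrame of strings from :data:`LABELS`, with the same
    day index and the same columns as the companion panel's ``X``.
    """

    user_id: str
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels.to_numpy(dtype=object))) - set(LABELS)
        if bad:
            raise PanelError(f"unknown labels {sorted(map(str, bad))!r}")

    @property
    def days(self) -> pd.DatetimeIndex:
        return self.labels.index

    def is_complete(self) -> bool:
        """True when no cell is left ``unlabeled``."""
        return not (self.labels.to_numpy(dtype=object) == UNLABELED).any()


@dataclass(frozen=True)
class Issue:
    """A structured validation finding; ``fatal`` issues preclude core use."""

    kind: str
    message: str
    fatal: bool = False


def _parse_dates(raw: pd.Series, origin: str) -> pd.DatetimeIndex:
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(raw, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise PanelError(f"unparseable date in {origin}: {exc}") from exc
    return idx


def _numeric_block(df: pd.DataFrame, cols: tuple[str, ...], origin: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PanelError(f"{origin}: columns {missing} not present in CSV")
    block = pd.DataFrame(index=df.index)
    for c in cols:
        try:
            block[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise PanelError(f"non-numeric value in column {c!r}: {exc}") from exc
    return block.astype(float)


def _panel_from_frame(df: pd.DataFrame, schema: PanelSchema, user_id: str) -> DailyPanel:
    idx = _parse_dates(df[schema.date], f"user {user_id!r}")
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique()
        raise PanelError(
            f"duplicate dates for user {user_id!r}: {[d.date().isoformat() for d in dups]}"
        )
    order = np.argsort(idx.values, kind="stable")
    df = df.iloc[order]
    idx = idx[order]
    X = _numeric_block(df, schema.x, "X").set_axis(idx, axis=0)
    W = _numeric_block(df, schema.w, "W").set_axis(idx, axis=0)
    Z = _numeric_block(df, schema.z, "Z").set_axis(idx, axis=0)
    return DailyPanel(user_id=user_id, X=X, W=W, Z=Z)


def read_daily_panel(path, schema: PanelSchema, user_id: str | None = None) -> DailyPanel:
    """Read one user's daily panel from a CSV file.

    Blank cells become NaN (technical missing), never 0.  Rows are sorted by
    date; duplicate dates, unmapped roles and non-numeric values raise
    :class:`PanelError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema.date not in df.columns:
        raise PanelError(f"date column {schema.date!r} not present in CSV")
    if schema.user_id is not None and schema.user_id in df.columns:
        ids = df[schema.user_id].unique()
        if len(ids) > 1:
            raise PanelError(
                f"CSV holds {len(ids)} users; use read_daily_panels for long format"
            )
        user_id = str(ids[0])
    return _panel_from_frame(df, schema, user_id if user_id is not None else str(path))


def read_daily_panels(path, schema: PanelSchema) -> dict[str, DailyPanel]:
    """Read a long-format multi-user CSV into per-user panels, keyed by id."""
    if schema.user_id is None:
        raise PanelError("long-format reading requires schema.user_id")
    df = pd.read_csv(path, float_precision="round_trip")
    if schema.user_id not in df.columns:
        raise PanelError(f"user-id column {schema.user_id!r} not present in CSV")
    out: dict[str, DailyPanel] = {}
    for uid, grp in df.groupby(schema.user_id, sort=True):
        out[str(uid)] = _panel_from_frame(grp, schema, str(uid))
    return out


def write_daily_panel(panel: DailyPanel, path, extra: pd.DataFrame | None = None) -> None:
    """Write a panel (and optional extra day-indexed columns) as CSV."""
    out = pd.concat([panel.X, panel.W, panel.Z], axis=1)
    if extra is not None:
        out = pd.concat([out, extra], axis=1)
    out.insert(0, "user_id", panel.user_id)
    out.index.name = "date"
    out.reset_index().assign(date=lambda d: d["date"].dt.date.astype(str)).to_csv(
        path, index=False
    )


def write_label_matrix(m: LabelMatrix, path) -> None:
    """Write a fully labeled matrix M as CSV (``<var>_label`` columns).

    Raises :class:`PanelError` if any cell is still ``unlabeled``.
    """
    if not m.is_complete():
        n = int((m.labels.to_numpy(dtype=object) == UNLABELED).sum())
        raise PanelError(f"label matrix has {n} unlabeled cells; run stage 2 first")
    out = m.labels.copy()
    out.columns = [f"{c}_label" for c in out.columns]
    out.insert(0, "user_id", m.user_id)
    out.index.name = "date"
    out.reset_index().assign(date=lambda d: d["date"].dt.date.astype(str)).to_csv(
        path, index=False
    )


def read_label_matrix(path) -> LabelMatrix:
    """Read back a label-matrix CSV written by :func:`write_label_matrix`."""
    df = pd.read_csv(path, float_precision="round_trip")
    idx = _parse_dates(df["date"], "label matrix")
    uid = str(df["user_id"].iloc[0]) if len(df) else ""
    cols = [c for c in df.columns if c.endswith("_label")]
    labels = df[cols].set_axis(idx, axis=0)
    labels.columns = [c[: -len("_label")] for c in cols]
    return LabelMatrix(user_id=uid, labels=labels.astype(object))


def validate_panel(p: DailyPanel) -> list[Issue]:
    """Report structural problems with a panel; never raises.

    Fatal issues (too few days, negative sensor activity, non-monotone dates)
    mean the two-stage algorithm must not be run; all-constant device-usage
    columns are flagged but not fatal.
    """
    issues: list[Issue] = []
    if p.T < MIN_DAYS:
        issues.append(
            Issue(
                "too_few_days",
                f"panel has T={p.T} days; at least {MIN_DAYS} required",
                fatal=True,
            )
        )
    if p.T > 1 and not p.days.is_monotonic_increasing:
        issues.append(Issue("non_monotone_dates", "days are not increasing", fatal=True))
    w = p.W.to_numpy(dtype=float)
    if np.nanmin(w, initial=np.inf) < 0:
        bad = [c for c in p.w_cols if (p.W[c].dropna() < 0).any()]
        issues.append(
            Issue(
                "negative_sensor_activity",
                f"negative values in sensor-activity columns {bad}",
                fatal=True,
            )
        )
    for c in p.z_cols:
        col = p.Z[c].dropna()
        if len(col) > 1 and float(col.std(ddof=1)) == 0.0:
            issues.append(
                Issue("constant_usage_column", f"device-usage column {c!r} is constant")
            )
    return issues
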