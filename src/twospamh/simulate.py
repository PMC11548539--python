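"""Synthetic per-user panels with known ground-truth device-use labels.

The generator emulates a smartphone step-count study: each simulated user has
a continuous activity level ``L_A`` and device-usage level ``L_U``, both in
[0, 1].  Each day first receives a true use/non-use status; hourly device-use
and physical-activity indicators are then drawn conditional on that status,
modulated by time-of-day weights (nights quiet, daytime busy, evenings in
between).  Hourly quantities — true steps, captured steps (only recorded in
hours when the device is in use, giving the characteristic downward bias),
uploads, screen unlocks — are aggregated to daily summaries:

* ``X``: ``step_count`` (captured) and ``active_minutes``;
* ``W``: ``n_uploads`` (UP) — sensor activity;
* ``Z``: ``screen_unlocks`` (SU), ``notifications`` (DN, arrives whether or
  not the phone is carried, hence a deliberately weak signal), and
  ``battery_variance`` (BV).

All randomness flows through ``numpy.random.default_rng`` (PCG64); every
entry point takes an explicit seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .panel import DailyPanel, MISSING, NON_MISSING


@dataclass(frozen=True)
class SimParams:
    """Numeric constants of the generator, centralized and overridable.

    ``p_use = p_use_base + p_use_slope * L_U`` is the daily probability of
    true device use.  Hourly rates are scaled by the time-of-day weight
    ``omega_h`` (night [0,6): ``omega_night``; day [8,22): ``omega_day``;
    otherwise ``omega_edge``).
    """

    p_use_base: float = 0.15
    p_use_slope: float = 0.70
    omega_night: float = 0.20
    omega_day: float = 1.00
    omega_edge: float = 0.60
    use_gain: float = 1.20          # hourly use prob = min(1, use_gain*L_U*omega)
    nonuse_hourly_p: float = 0.05   # residual hourly use prob on non-use days
    steps_per_active_hour: float = 600.0   # Poisson mean when active
    upload_capture_p: float = 0.90  # P(an in-use hour produces an upload)
    unlock_rate: float = 2.0        # per-hour Poisson mean scale for unlocks
    notification_rate: float = 20.0  # daily Poisson mean scale
    battery_shape: float = 2.0
    battery_scale_base: float = 1.0
    battery_scale_slope: float = 4.0
    active_minutes_beta: tuple[float, float] = (5.0, 2.0)
    hours_per_day: int = 24

    def omega(self) -> np.ndarray:
        """Time-of-day weight per hour 0..23."""
        h = np.arange(self.hours_per_day)
        w = np.full(self.hours_per_day, self.omega_edge)
        w[(h >= 0) & (h < 6)] = self.omega_night
        w[(h >= 8) & (h < 22)] = self.omega_day
        return w


@dataclass(frozen=True)
class SimConfig:
    """One simulated user: activity level, usage level, horizon and seed."""

    la: float
    lu: float
    T: int = 100
    seed: int | np.random.SeedSequence = 0
    user_id: str = "sim_user"
    start_date: str = "2021-01-01"
    params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.la <= 1.0 and 0.0 <= self.lu <= 1.0):
            raise ValueError("activity and usage levels must lie in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class GroundTruth:
    """True daily device-use labels plus generator-side diagnostics."""

    labels: np.ndarray                 # length T, values missing / non_missing
    true_daily_steps: np.ndarray       # steps the user actually took
    captured_daily_steps: np.ndarray   # steps the device recorded

    @property
    def as_series(self) -> pd.Series:  # pragma: no cover - convenience
        return pd.Series(self.labels)


def _simulate_arrays(cfg: SimConfig, rng: np.random.Generator):
    p = cfg.params
    T, H = cfg.T, p.hours_per_day
    omega = p.omega()

    p_use = p.p_use_base + p.p_use_slope * cfg.lu
    truth = np.where(rng.random(T) < p_use, NON_MISSING, MISSING).astype(object)

    use_p = np.where(
        (truth == NON_MISSING)[:, None],
        np.minimum(1.0, p.use_gain * cfg.lu * omega)[None, :],
        p.nonuse_hourly_p,
    )
    U = rng.random((T, H)) < use_p
    A = rng.random((T, H)) < np.minimum(1.0, cfg.la * omega)[None, :]

    true_hourly_steps = np.where(A, rng.poisson(p.steps_per_active_hour, (T, H)), 0)
    captured_hourly = np.where(U, true_hourly_steps, 0)

    uploads = (U & (rng.random((T, H)) < p.upload_capture_p)).sum(axis=1)
    unlocks = np.where(
        U, rng.poisson(np.broadcast_to(p.unlock_rate * cfg.lu * omega, (T, H))), 0
    ).sum(axis=1)
    notifications = rng.poisson(p.notification_rate * cfg.lu, T)
    battery = rng.gamma(
        p.battery_shape, p.battery_scale_base + p.battery_scale_slope * U.sum(axis=1) / H
    )
    a, b = p.active_minutes_beta
    active_minutes = np.where(A & U, 60.0 * rng.beta(a, b, (T, H)), 0.0).sum(axis=1)

    return truth, true_hourly_steps.sum(axis=1), captured_hourly.sum(axis=1), uploads, \
        unlocks, notifications, battery, active_minutes


def simulate_user(cfg: SimConfig) -> tuple[DailyPanel, GroundTruth]:
    """Simulate one user's panel and its ground truth, reproducibly.

    If a draw of the daily truth comes out single-class (possible only at
    extreme usage levels or tiny T), the whole user is redrawn from a spawned
    sub-seed so that sensitivity and specificity are both defined.
    """
    seed_seq = (
        cfg.seed
        if isinstance(cfg.seed, np.random.SeedSequence)
        else np.random.SeedSequence(cfg.seed)
    )
    for attempt in range(100):
        rng = np.random.default_rng(seed_seq)
        (truth, true_steps, captured, uploads, unlocks, notifications, battery,
         active_minutes) = _simulate_arrays(cfg, rng)
        if cfg.T == 1 or ((truth == MISSING).any() and (truth == NON_MISSING).any()):
            break
        seed_seq = seed_seq.spawn(1)[0]

    days = pd.date_range(cfg.start_date, periods=cfg.T, freq="D")
    panel = DailyPanel(
        user_id=cfg.user_id,
        X=pd.DataFrame(
            {"step_count": captured.astype(float), "active_minutes": active_minutes},
            index=days,
        ),
        W=pd.DataFrame({"n_uploads": uploads.astype(float)}, index=days),
        Z=pd.DataFrame(
            {
                "screen_unlocks": unlocks.astype(float),
                "notifications": notifications.astype(float),
                "battery_variance": battery,
            },
            index=days,
        ),
    )
    truth_obj = GroundTruth(
        labels=truth, true_daily_steps=true_steps, captured_daily_steps=captured
    )
    return panel, truth_obj


DEFAULT_GRID = tuple(np.round(np.arange(0.3, 0.81, 0.1), 1))


@dataclass
class GridCell:
    """One simulated dataset: a grid cell, its replicate index, panel, truth."""

    la: float
    lu: float
    rep: int
    config: SimConfig
    panel: DailyPanel
    truth: GroundTruth


def simulate_grid(
    la_values=DEFAULT_GRID,
    lu_values=DEFAULT_GRID,
    T: int = 100,
    reps: int = 1,
    seed: int = 0,
    params: SimParams | None = None,
) -> Iterator[GridCell]:
    """Simulate one user per (L_A, L_U) cell, ``reps`` panels per user.

    The default 6x6 grid spans 0.3..0.8 in steps of 0.1: 36 users, 100 days
    each, hence 3600 user-days per replicate.  Sub-seeding from
    ``(seed, cell, rep)`` makes every panel individually reproducible.
    """
    params = params or SimParams()
    for i, la in enumerate(la_values):
        for j, lu in enumerate(lu_values):
            for rep in range(reps):
                ss = np.random.SeedSequence([int(seed), i, j, rep])
                cfg = SimConfig(
                    la=float(la), lu=float(lu), T=T, seed=ss,
                    user_id=f"u_la{la:g}_lu{lu:g}", params=params,
                )
                panel, truth = simulate_user(cfg)
                yield GridCell(
                    la=float(la), lu=float(lu), rep=rep, config=cfg,
                    panel=panel, truth=truth,
                )
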