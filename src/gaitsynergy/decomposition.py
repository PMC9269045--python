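"""Decomposition index (DI) for the hip–knee joint pair.

A decomposition movement occurs when exactly one joint of a pair moves
while the other pauses.  A joint is paused at a grid point when its
angular velocity magnitude is strictly below 5 deg/s; the DI is the
fraction of the gait cycle spent in decomposition (T_dec / T_gait).
Stance and swing DIs are normalized by the respective phase duration so
each can independently approach 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import (
    JointTrajectory,
    NormalizedCycle,
    PCT_GRID,
    fit_sinusoid_sum,
    normalize_cycle,
    segment_cycles,
)

PAUSE_THRESHOLD_DPS = 5.0


@dataclass
class VelocitySeries:
    """Angular velocity (deg/s) on the 101-point cycle-percent grid."""

    omega: np.ndarray
    stride_duration: float  # s


@dataclass
class DIResult:
    di_whole: float
    di_stance: float
    di_swing: float
    pair: tuple[str, str] = ("hip", "knee")
    side: str = ""
    threshold: float = PAUSE_THRESHOLD_DPS

    def __post_init__(self) -> None:
        for v in (self.di_whole, self.di_stance, self.di_swing):
            if not 0.0 <= v <= 1.0:
                raise ValueError("decomposition indices must lie in [0, 1]")


def angular_velocity(cycle: NormalizedCycle, stride_duration: float) -> VelocitySeries:
    """Finite-difference angular velocity of a normalized cycle.

    Central differences on the 101-point grid (one-sided at the
    endpoints), converted to deg/s via the stride duration.
    """
    if stride_duration <= 0:
        raise ValueError("stride_duration must be > 0")
    dpct = PCT_GRID[1] - PCT_GRID[0]
    omega = np.gradient(cycle.angle, dpct) * (100.0 / stride_duration)
    return VelocitySeries(omega, stride_duration)


def pause_mask(v: VelocitySeries, threshold: float = PAUSE_THRESHOLD_DPS) -> np.ndarray:
    """True where the joint is paused: |omega| strictly below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return np.abs(v.omega) < threshold


def decomposition_index(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    stance_end_pct: float,
    pair: tuple[str, str] = ("hip", "knee"),
    side: str = "",
    threshold: float = PAUSE_THRESHOLD_DPS,
) -> DIResult:
    """DI over the whole cycle and per phase from two pause masks.

    Decomposition at a grid point requires exactly one paused joint
    (exclusive-or); both-paused and both-moving points do not count.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("pause masks differ in length")
    decomposed = mask_a ^ mask_b
    n = len(decomposed)
    pct = np.linspace(0.0, 100.0, n)
    stance = pct <= stance_end_pct
    swing = ~stance
    if stance.sum() == 0 or swing.sum() == 0:
        raise ValueError("stance or swing window is empty")
    return DIResult(
        di_whole=float(decomposed.mean()),
        di_stance=float(decomposed[stance].mean()),
        di_swing=float(decomposed[swing].mean()),
        pair=pair,
        side=side,
        threshold=threshold,
    )


def cycle_di(
    hip: NormalizedCycle,
    knee: NormalizedCycle,
    stride_duration: float,
    threshold: float = PAUSE_THRESHOLD_DPS,
    smooth_order: int | None = None,
) -> DIResult:
    """Hip–knee DI of one normalized cycle pair.

    With ``smooth_order`` set, both curves are harmonically smoothed at
    that order before differentiation (suppresses noise-driven
    threshold chatter); ``None`` uses the raw curves.
    """
    if smooth_order is not None:
        _, hip = fit_sinusoid_sum(hip, smooth_order)
        _, knee = fit_sinusoid_sum(knee, smooth_order)
    v_hip = angular_velocity(hip, stride_duration)
    v_knee = angular_velocity(knee, stride_duration)
    return decomposition_index(
        pause_mask(v_hip, threshold),
        pause_mask(v_knee, threshold),
        hip.stance_end_pct,
        side=hip.side,
        threshold=threshold,
    )


def trial_di(
    trial,
    side: str,
    threshold: float = PAUSE_THRESHOLD_DPS,
    smooth_order: int | None = 12,
) -> DIResult:
    """Mean hip–knee DI over all cycles of a synthetic or imported trial.

    The trial is segmented at its ground-truth heel strikes, each cycle
    normalized to the 101-point grid, smoothed (default harmonic order
    12) and differentiated; per-cycle DIs are averaged.
    """
    from .pipeline import trial_cycles  # local import avoids a cycle

    cycles = trial_cycles(trial, side)
    results = [
        cycle_di(hip, knee, trial.profile.stride_duration, threshold, smooth_order)
        for hip, knee in cycles
    ]
    if not results:
        raise ValueError("no complete cycles in trial")
    return DIResult(
        di_whole=float(np.mean([r.di_whole for r in results])),
        di_stance=float(np.mean([r.di_stance for r in results])),
        di_swing=float(np.mean([r.di_swing for r in results])),
        side=side,
        threshold=threshold,
    )
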