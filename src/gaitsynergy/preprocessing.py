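"""Gait-cycle segmentation, time normalization and harmonic smoothing.

The preparation chain for synergy analysis: a continuous joint-angle
recording is cut into gait cycles (heel strike to heel strike), each
cycle is resampled onto the 0–100% axis (101 points, both endpoints
on-grid), and the normalized curve is smoothed by least-squares fitting
of a sum of sinusoids at stride-frequency multiples, which removes
riding waves and measurement unevenness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

PCT_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class JointTrajectory:
    """A uniformly sampled joint-angle series for one joint of one limb."""

    angle: np.ndarray  # degrees
    sampling_rate: float  # Hz
    joint: str = "hip"
    side: str = "right"
    heel_strikes: np.ndarray | None = None  # sample indices
    toe_offs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for ev in (self.heel_strikes, self.toe_offs):
            if ev is not None and np.any(np.diff(ev) <= 0):
                raise ValueError("event indices must be strictly increasing")


@dataclass
class NormalizedCycle:
    """One gait cycle on the 0–100% grid with its stance/swing boundary."""

    angle: np.ndarray  # degrees, 101 points
    stance_end_pct: float
    joint: str = "hip"
    side: str = "right"

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.angle.shape != (101,):
            raise ValueError("normalized cycle must have exactly 101 points")
        if not 0.0 < self.stance_end_pct < 100.0:
            raise ValueError("stance_end_pct must lie in (0, 100)")


@dataclass
class SinusoidFit:
    """Amplitude/phase form of a harmonic least-squares fit.

    The fitted curve is ``mean_offset + sum_k amplitude[k-1] *
    sin(2*pi*k*t/100 + phase[k-1])`` for t in percent.
    """

    mean_offset: float
    amplitude: np.ndarray  # degrees, per harmonic 1..K
    phase: np.ndarray  # radians, per harmonic 1..K
    residual_rms: float
    fundamental_period: float = 100.0

    @property
    def order(self) -> int:
        return len(self.amplitude)

    def evaluate(self, pct: np.ndarray) -> np.ndarray:
        pct = np.asarray(pct, dtype=float)
        out = np.full(pct.shape, self.mean_offset)
        for k in range(1, self.order + 1):
            out = out + self.amplitude[k - 1] * np.sin(
                2.0 * np.pi * k * pct / self.fundamental_period + self.phase[k - 1]
            )
        return out


def dominant_period(x: np.ndarray, min_lag: int) -> int:
    """Dominant period in samples from the autocorrelation peak."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    if n < 2 * min_lag or np.allclose(x, 0.0):
        raise ValueError("series too short or constant; no dominant period")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec))[: n // 2 + 1]
    acf /= acf[0]
    lo, hi = min_lag, len(acf) - 1
    if hi <= lo:
        raise ValueError("series too short for the requested minimum lag")
    # first local maximum past min_lag that carries substantial correlation
    seg = acf[lo:hi]
    peaks, _ = find_peaks(seg, height=0.2)
    if len(peaks) == 0:
        lag = lo + int(np.argmax(seg))
    else:
        # tallest among the first few peaks guards against a spurious
        # bump at half the stride period
        cands = peaks[:3]
        lag = lo + int(cands[np.argmax(seg[cands])])
    return lag


def segment_cycles(traj: JointTrajectory) -> list[tuple[int, int]]:
    """Cut a trajectory into heel-strike-to-heel-strike intervals.

    With events attached the intervals are consecutive heel-strike
    pairs.  Without events, heel strikes are detected as hip-angle
    local maxima (maximum hip flexion closely precedes heel strike in
    level walking) separated by at least half the dominant period.
    """
    if traj.heel_strikes is not None and len(traj.heel_strikes) >= 2:
        hs = np.asarray(traj.heel_strikes, dtype=int)
        return [(int(a), int(b)) for a, b in zip(hs[:-1], hs[1:])]
    min_lag = max(8, int(0.3 * traj.sampling_rate))
    period = dominant_period(traj.angle, min_lag)
    peaks, _ = find_peaks(traj.angle, distance=max(2, int(0.5 * period)))
    if len(peaks) < 2:
        raise ValueError("fewer than 2 heel strikes detectable")
    return [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]


def normalize_cycle(
    traj: JointTrajectory, interval: tuple[int, int], toe_off: int
) -> NormalizedCycle:
    """Resample one cycle onto the 101-point 0–100% grid."""
    start, end = interval
    if not (0 <= start < end < len(traj.angle)):
        raise ValueError("interval out of range")
    if not start < toe_off < end:
        raise ValueError("toe_off must lie strictly inside the interval")
    src = np.arange(start, end + 1, dtype=float)
    grid = start + (end - start) * PCT_GRID / 100.0
    angle = np.interp(grid, src, traj.angle[start : end + 1])
    stance_end = 100.0 * (toe_off - start) / (end - start)
    return NormalizedCycle(angle, stance_end, joint=traj.joint, side=traj.side)


def fit_sinusoid_sum(cycle: NormalizedCycle, order: int = 6) -> tuple[SinusoidFit, NormalizedCycle]:
    """Least-squares harmonic fit of a normalized cycle.

    Fits an intercept plus sine/cosine pairs at harmonics 1..``order``
    of the cycle frequency on the 101-point grid and returns the
    amplitude/phase form together with the smoothed cycle.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order > 49:
        raise ValueError("order > 49 is rank-deficient on the 101-point grid")
    t = PCT_GRID
    cols = [np.ones_like(t)]
    for k in range(1, order + 1):
        w = 2.0 * np.pi * k * t / 100.0
        cols.extend([np.sin(w), np.cos(w)])
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, cycle.angle, rcond=None)
    smooth = design @ beta
    resid = cycle.angle - smooth
    b_sin = beta[1::2]
    b_cos = beta[2::2]
    fit = SinusoidFit(
        mean_offset=float(beta[0]),
        amplitude=np.hypot(b_sin, b_cos),
        phase=np.arctan2(b_cos, b_sin),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
    smoothed = NormalizedCycle(smooth, cycle.stance_end_pct, joint=cycle.joint, side=cycle.side)
    return fit, smoothed


def representative_cycle(cycles: list[NormalizedCycle]) -> NormalizedCycle:
    """Pick the cycle closest (RMSE) to the within-trial mean curve."""
    if not cycles:
        raise ValueError("no cycles supplied")
    stack = np.stack([c.angle for c in cycles])
    mean = stack.mean(axis=0)
    rmse = np.sqrt(np.mean((stack - mean) ** 2, axis=1))
    return cycles[int(np.argmin(rmse))]
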