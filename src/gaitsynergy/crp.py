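"""Continuous relative phase (CRP) between joint-angle curves.

The instantaneous phase of a mean-centered normalized cycle is taken
from its discrete Hilbert analytic signal; CRP between two curves is
the pointwise phase difference wrapped to (-180, 180].  Two CRP curves
are compared by root-mean-square error (on wrapped, smallest-angle
differences) and Pearson correlation, over the whole cycle or
restricted to stance or swing.

The phase angle uses the four-quadrant arctangent atan2(H(x), x): the
printed two-quadrant arctan form cannot represent a full phase cycle.
Under this convention the phase of cos(2*pi*t/T) advances by +90
degrees over a quarter period, and a signal that lags another by a
quarter period yields a CRP of +90 degrees when passed as the second
argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocessing import NormalizedCycle, PCT_GRID


def wrap_degrees(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-180, 180]."""
    return -((-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class PhaseSeries:
    """Instantaneous phase (degrees) of one normalized cycle."""

    phi: np.ndarray  # degrees in (-180, 180], 101 points
    label: str = ""
    stance_end_pct: float = 50.0


@dataclass
class CRPSeries:
    """Continuous relative phase curve between two signals."""

    crp: np.ndarray  # degrees in (-180, 180], 101 points
    pair_label: tuple[str, str] = ("", "")
    stance_end_pct: float = 50.0


@dataclass
class CRPComparison:
    rmse: float  # degrees
    pcc: float  # may be nan if a window has zero variance
    window: str = "whole"
    n_points: int = 101


class DegenerateSignalError(ValueError):
    """Raised when a phase is requested for a (near-)constant signal."""


def analytic_phase(cycle: NormalizedCycle, label: str = "") -> PhaseSeries:
    """Hilbert-transform phase angle of a normalized cycle.

    The cycle is mean-centered; the analytic signal is built by the
    discrete (FFT-based) Hilbert transform on the 101-point grid and
    the phase is atan2(H(x), x) in degrees.
    """
    x = cycle.angle - np.mean(cycle.angle)
    if np.ptp(x) < 1e-9 or np.std(x) < 1e-12:
        raise DegenerateSignalError("phase undefined for a constant signal")
    analytic = hilbert(x)
    phi = np.degrees(np.arctan2(analytic.imag, x))
    return PhaseSeries(wrap_degrees(phi), label=label, stance_end_pct=cycle.stance_end_pct)


def crp(phi1: PhaseSeries, phi2: PhaseSeries) -> CRPSeries:
    """CRP(t) = phi1(t) - phi2(t), wrapped to (-180, 180]."""
    if phi1.phi.shape != phi2.phi.shape:
        raise ValueError("phase series are on different grids")
    return CRPSeries(
        wrap_degrees(phi1.phi - phi2.phi),
        pair_label=(phi1.label, phi2.label),
        stance_end_pct=phi1.stance_end_pct,
    )


def _window_slice(stance_end_pct: float, window: str, n: int = 101) -> np.ndarray:
    pct = np.linspace(0.0, 100.0, n)
    if window == "whole":
        mask = np.ones(n, dtype=bool)
    elif window == "stance":
        mask = pct <= stance_end_pct
    elif window == "swing":
        mask = pct > stance_end_pct
    else:
        raise ValueError(f"unknown window {window!r}")
    return mask


def crp_compare(c1: CRPSeries, c2: CRPSeries, window: str = "whole") -> CRPComparison:
    """RMSE and Pearson correlation between two CRP curves.

    RMSE uses the wrapped (smallest-angle) pointwise difference; the
    window ("whole", "stance", "swing") is resolved with ``c1``'s
    stance/swing boundary.
    """
    if c1.crp.shape != c2.crp.shape:
        raise ValueError("CRP series are on different grids")
    mask = _window_slice(c1.stance_end_pct, window, n=len(c1.crp))
    if mask.sum() < 3:
        raise ValueError(f"window {window!r} contains fewer than 3 grid points")
    a, b = c1.crp[mask], c2.crp[mask]
    diff = wrap_degrees(a - b)
    rmse = float(np.sqrt(np.mean(diff**2)))
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])
    return CRPComparison(rmse=rmse, pcc=pcc, window=window, n_points=int(mask.sum()))


def subject_crp_profile(
    cycles: dict[tuple[str, str], NormalizedCycle], pairing: str
) -> list[CRPSeries]:
    """CRP curves for one subject's set of normalized cycles.

    ``cycles`` maps (side, joint) to a normalized cycle.  Intralimb
    pairing yields CRP(hip, knee) per side (hip as signal 1);
    interlimb pairing yields, per joint, the CRP between the two sides
    (sound/right side as signal 1), plus their pointwise circular mean
    labelled "interlimb_mean" as the summary series.
    """
    sides = sorted({s for s, _ in cycles})
    joints = sorted({j for _, j in cycles})
    out: list[CRPSeries] = []
    if pairing == "intralimb":
        for side in sides:
            if (side, "hip") not in cycles or (side, "knee") not in cycles:
                raise ValueError(f"intralimb pairing needs hip and knee for side {side!r}")
            p_hip = analytic_phase(cycles[(side, "hip")], label=f"{side}_hip")
            p_knee = analytic_phase(cycles[(side, "knee")], label=f"{side}_knee")
            out.append(crp(p_hip, p_knee))
    elif pairing == "interlimb":
        if len(sides) != 2:
            raise ValueError("interlimb pairing needs both sides")
        s1, s2 = ("right", "left") if set(sides) == {"right", "left"} else sides
        per_joint = []
        for joint in joints:
            p1 = analytic_phase(cycles[(s1, joint)], label=f"{s1}_{joint}")
            p2 = analytic_phase(cycles[(s2, joint)], label=f"{s2}_{joint}")
            per_joint.append(crp(p1, p2))
        out.extend(per_joint)
        stack = np.stack([c.crp for c in per_joint])
        mean = circular_mean(stack, axis=0)
        out.append(
            CRPSeries(mean, pair_label=("interlimb_mean", ""), stance_end_pct=per_joint[0].stance_end_pct)
        )
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return out


def circular_mean(deg: np.ndarray, axis: int = 0) -> np.ndarray:
    """Pointwise circular mean of angle arrays in degrees."""
    rad = np.radians(deg)
    return wrap_degrees(
        np.degrees(np.arctan2(np.sin(rad).mean(axis=axis), np.cos(rad).mean(axis=axis)))
    )


def plot_crp(series: CRPSeries, ax=None, **kwargs):
    """Plot one CRP curve over the gait cycle with its stance boundary."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    pct = np.linspace(0.0, 100.0, len(series.crp))
    ax.plot(pct, series.crp, **kwargs)
    ax.axvline(series.stance_end_pct, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("gait cycle (%)")
    ax.set_ylabel("CRP (deg)")
    if any(series.pair_label):
        ax.set_title(" vs ".join(filter(None, series.pair_label)))
    return ax


def mean_crp_curve(series: list[CRPSeries]) -> CRPSeries:
    """Circular pointwise mean of several CRP curves (a group reference)."""
    if not series:
        raise ValueError("no CRP series supplied")
    stack = np.stack([s.crp for s in series])
    stance = float(np.mean([s.stance_end_pct for s in series]))
    return CRPSeries(circular_mean(stack, axis=0), pair_label=("reference", ""), stance_end_pct=stance)
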