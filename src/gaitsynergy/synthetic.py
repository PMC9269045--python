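"""Seeded synthetic gait trials emulating healthy, stroke and amputee walking.

Joint-angle waveforms are band-limited sums of sinusoids at
stride-frequency multiples: the hip is a cosine series peaking at heel
strike (maximum flexion), the knee a two-bump curve (stance-flexion
bump plus a dominant swing-flexion peak placed inside the swing
window).  Trials tile these cycles at the profile's sampling rate,
shift the contralateral limb by half a cycle, impose zero-order-hold
pause windows (with cosine-tapered edges centered on the window
boundaries) and add Gaussian measurement noise.  Thigh inertial
channels are derived from the thigh segment angle (hip flexion from
vertical) with a gravity-consistent acceleration model at a sensor
offset below the hip.

Everything is deterministic given (profile, n_cycles, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import PCT_GRID, NormalizedCycle
from .profiles import GaitProfile, PauseWindow, SIDES, jitter_profile, make_profile

GRAVITY = 9.81  # m/s^2
THIGH_SENSOR_OFFSET = 0.25  # m below the hip joint
PAUSE_TAPER_SAMPLES = 5


@dataclass
class FourierCurve:
    """A periodic curve c0 + sum_k a_k cos(2*pi*k*t) + b_k sin(2*pi*k*t), t in cycles."""

    c0: float
    a: np.ndarray
    b: np.ndarray

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full(phase.shape, self.c0)
        for k in range(1, len(self.a) + 1):
            w = 2.0 * np.pi * k * phase
            out = out + self.a[k - 1] * np.cos(w) + self.b[k - 1] * np.sin(w)
        return out


def _project_harmonics(values: np.ndarray, order: int) -> FourierCurve:
    """Project a densely sampled periodic curve onto harmonics 1..order."""
    n = len(values)
    spec = np.fft.rfft(values) / n
    a = 2.0 * spec[1 : order + 1].real
    b = -2.0 * spec[1 : order + 1].imag
    return FourierCurve(float(spec[0].real), a, b)


def _periodic_bump(phase: np.ndarray, center: float, kappa: float) -> np.ndarray:
    return np.exp(kappa * (np.cos(2.0 * np.pi * (phase - center)) - 1.0))


def hip_curve(profile: GaitProfile, side: str, rng: np.random.Generator) -> FourierCurve:
    """Unit-scale hip flexion waveform, maximum exactly at heel strike."""
    k = profile.harmonic_count
    base = np.array([1.0, 0.12, 0.05, 0.02][:k] + [0.01] * max(0, k - 4))
    pert = 1.0 + 0.08 * rng.standard_normal(len(base))
    pert[0] = 1.0
    amps = np.abs(base * pert)
    # all-cosine positive series -> global maximum at phase 0
    return FourierCurve(0.0, amps, np.zeros_like(amps))


def knee_curve(profile: GaitProfile, side: str, rng: np.random.Generator) -> FourierCurve:
    """Unit-scale knee flexion waveform: stance bump + swing peak."""
    stance_frac = 1.0 - profile.swing_percentage[side]
    c_stance = 0.35 * stance_frac
    c_swing = stance_frac + 0.45 * profile.swing_percentage[side]
    c_stance += 0.01 * rng.standard_normal()
    c_swing += 0.01 * rng.standard_normal()
    amp_stance = 0.30 * (1.0 + 0.05 * rng.standard_normal())
    dense = np.linspace(0.0, 1.0, 1024, endpoint=False)
    raw = amp_stance * _periodic_bump(dense, c_stance, 40.0) + _periodic_bump(
        dense, c_swing, 18.0
    )
    return _project_harmonics(raw, profile.harmonic_count)


def _rescale(values: np.ndarray, rom: float) -> np.ndarray:
    ptp = float(np.ptp(values))
    if ptp <= 0:
        raise ValueError("degenerate waveform with zero range")
    centered = values - values.mean()
    return centered * (rom / ptp)


def generate_cycle(
    profile: GaitProfile, side: str, seed: int
) -> tuple[NormalizedCycle, NormalizedCycle]:
    """One noiseless normalized (hip, knee) cycle pair for ``side``.

    Peak-to-peak amplitudes equal the profile ranges of motion exactly
    on the 101-point grid.
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    rng = np.random.default_rng(seed)
    hip = hip_curve(profile, side, rng)
    knee = knee_curve(profile, side, rng)
    phase = PCT_GRID / 100.0
    stance_end = profile.stance_end_pct(side)
    hip_angle = _rescale(hip(phase), profile.rom_hip[side])
    knee_angle = _rescale(knee(phase), profile.rom_knee[side])
    return (
        NormalizedCycle(hip_angle, stance_end, joint="hip", side=side),
        NormalizedCycle(knee_angle, stance_end, joint="knee", side=side),
    )


def _apply_pauses(
    template: np.ndarray, windows: list[tuple[float, float]], taper: int
) -> np.ndarray:
    """Zero-order-hold pause windows with cosine ramps centered on the edges."""
    spc = len(template)
    out = template.astype(float).copy()
    for start_pct, end_pct in windows:
        i0 = int(round(start_pct / 100.0 * spc))
        i1 = int(round(end_pct / 100.0 * spc))
        if i1 <= i0:
            continue
        hold = template[i0]
        # full hold over the ground-truth window; cosine ease-in/out
        # ramps sit outside it so the held duration is not shortened
        w = np.zeros(spc)
        w[i0:i1] = 1.0
        ramp_up = np.arange(max(0, i0 - taper), i0)
        if len(ramp_up):
            w[ramp_up] = 0.5 * (1.0 - np.cos(np.pi * (ramp_up - (i0 - taper)) / taper))
        ramp_dn = np.arange(i1, min(spc, i1 + taper))
        if len(ramp_dn):
            w[ramp_dn] = np.maximum(
                w[ramp_dn], 0.5 * (1.0 + np.cos(np.pi * (ramp_dn - i1 + 1) / taper))
            )
        out = (1.0 - w) * out + w * hold
    return out


@dataclass
class SyntheticTrial:
    """A multi-cycle two-sided synthetic gait recording with ground truth."""

    angles: dict[tuple[str, str], np.ndarray]  # (side, joint) -> degrees
    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    thigh_gyro: dict[str, np.ndarray]  # deg/s
    thigh_acc: dict[str, np.ndarray]  # (N, 3) m/s^2
    profile: GaitProfile
    pause_windows: tuple[PauseWindow, ...]
    seed: int
    samples_per_cycle: int

    @property
    def sampling_rate(self) -> float:
        return self.profile.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.angles.values())))

    def events(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        return self.heel_strikes[side], self.toe_offs[side]


def generate_trial(profile: GaitProfile, n_cycles: int, seed: int) -> SyntheticTrial:
    """Generate a continuous two-sided trial of ``n_cycles`` gait cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    fs = profile.sampling_rate
    spc = max(8, int(round(profile.stride_duration * fs)))
    n = n_cycles * spc
    phase = np.arange(spc, dtype=float) / spc

    offset = {"right": 0.0, "left": profile.phase_offset_between_limbs}
    curve_fns = {"hip": hip_curve, "knee": knee_curve}

    angles: dict[tuple[str, str], np.ndarray] = {}
    clean_hip: dict[str, np.ndarray] = {}
    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    thigh_gyro: dict[str, np.ndarray] = {}
    thigh_acc: dict[str, np.ndarray] = {}

    # one waveform seed per (side, joint): deterministic fan-out
    wave_rngs = {
        (side, joint): np.random.default_rng([seed, si, ji])
        for si, side in enumerate(SIDES)
        for ji, joint in enumerate(("hip", "knee"))
    }

    for side in SIDES:
        roll = int(round(offset[side] * spc))
        rom = {"hip": profile.rom_hip[side], "knee": profile.rom_knee[side]}
        for joint in ("hip", "knee"):
            curve = curve_fns[joint](profile, side, wave_rngs[(side, joint)])
            template = curve(phase)
            windows = [
                (w.start_pct, w.end_pct)
                for w in profile.pause_spec
                if w.side == side and w.joint == joint
            ]
            template = _apply_pauses(template, windows, PAUSE_TAPER_SAMPLES)
            template = _rescale(template, rom[joint])
            series = np.roll(np.tile(template, n_cycles), roll)
            if joint == "hip":
                clean_hip[side] = series.copy()
            angles[(side, joint)] = series

        hs = roll + spc * np.arange(-1, n_cycles + 1)
        to = hs + int(round((1.0 - profile.swing_percentage[side]) * spc))
        heel_strikes[side] = hs[(hs >= 0) & (hs < n)]
        toe_offs[side] = to[(to >= 0) & (to < n)]

        # thigh inertial channels from the noiseless thigh segment angle
        theta = np.radians(clean_hip[side])
        omega = np.gradient(theta) * fs  # rad/s
        alpha = np.gradient(omega) * fs  # rad/s^2
        thigh_gyro[side] = np.degrees(omega)
        acc = np.column_stack(
            [
                GRAVITY * np.cos(theta) + THIGH_SENSOR_OFFSET * omega**2,
                GRAVITY * np.sin(theta) + THIGH_SENSOR_OFFSET * alpha,
                np.zeros(n),
            ]
        )
        thigh_acc[side] = acc

    if profile.noise_sd > 0:
        for key in angles:
            angles[key] = angles[key] + rng.normal(0.0, profile.noise_sd, n)
        for side in SIDES:
            thigh_gyro[side] = thigh_gyro[side] + rng.normal(0.0, profile.noise_sd, n)
            thigh_acc[side] = thigh_acc[side] + rng.normal(
                0.0, 0.02 * profile.noise_sd, (n, 3)
            )

    return SyntheticTrial(
        angles=angles,
        heel_strikes=heel_strikes,
        toe_offs=toe_offs,
        thigh_gyro=thigh_gyro,
        thigh_acc=thigh_acc,
        profile=profile,
        pause_windows=tuple(profile.pause_spec),
        seed=seed,
        samples_per_cycle=spc,
    )


def make_cohort(
    group_label: str,
    n_subjects: int,
    seed: int,
    n_cycles: int = 10,
    overrides: dict | None = None,
    jitter_sd: float = 0.05,
) -> dict[str, SyntheticTrial]:
    """A cohort of subjects: jittered group profile, one trial each."""
    base = make_profile(group_label, overrides)
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n_subjects)
    cohort = {}
    for i in range(n_subjects):
        prof = jitter_profile(base, int(states[2 * i] % 2**31), sd=jitter_sd)
        trial = generate_trial(prof, n_cycles, int(states[2 * i + 1] % 2**31))
        cohort[f"S{i + 1:02d}"] = trial
    return cohort
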