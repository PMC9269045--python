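"""Group-level gait profiles for the synthetic generator.

A :class:`GaitProfile` collects the per-group walking parameters (speed,
stride duration, swing percentage, hip/knee ranges of motion, imposed
pause windows) that the synthetic generator turns into multi-cycle
joint-angle trials.  Defaults for the three groups — healthy, stroke and
transfemoral amputee — follow published group means for self-selected
level walking; patient groups carry distinct parameters for the sound
and affected sides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

SIDES = ("right", "left")
JOINTS = ("hip", "knee")

GROUPS = ("healthy", "stroke", "amputee")


class PauseWindow(NamedTuple):
    """A window of the gait cycle over which one joint is held constant.

    ``start_pct``/``end_pct`` are in percent of that side's own cycle
    (heel strike = 0%).
    """

    side: str
    joint: str
    start_pct: float
    end_pct: float


@dataclass(frozen=True)
class GaitProfile:
    """Parameter set describing one walking condition.

    Per-side parameters are mappings ``{"right": ..., "left": ...}``.
    ``swing_percentage`` is the fraction of the cycle spent in swing;
    stance therefore ends at ``(1 - swing_percentage) * 100`` percent.
    """

    group_label: str
    side_roles: dict[str, str]
    speed: float  # m/s
    stride_duration: float  # s
    swing_percentage: dict[str, float]
    rom_hip: dict[str, float]  # degrees, peak-to-peak
    rom_knee: dict[str, float]  # degrees, peak-to-peak
    harmonic_count: int = 4
    pause_spec: tuple[PauseWindow, ...] = ()
    phase_offset_between_limbs: float = 0.5  # fraction of cycle
    noise_sd: float = 0.5  # degrees
    sampling_rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.stride_duration <= 0:
            raise ValueError("stride_duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.harmonic_count < 1:
            raise ValueError("harmonic_count must be >= 1")
        for side in SIDES:
            if not 0 < self.swing_percentage[side] < 1:
                raise ValueError("swing_percentage must lie in (0, 1)")
            if self.rom_hip[side] <= 0 or self.rom_knee[side] <= 0:
                raise ValueError("ranges of motion must be > 0")
        seen: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for w in self.pause_spec:
            if w.side not in SIDES or w.joint not in JOINTS:
                raise ValueError(f"pause window references unknown {w.side}/{w.joint}")
            if not 0 <= w.start_pct < w.end_pct <= 100:
                raise ValueError("pause window must satisfy 0 <= start < end <= 100")
            for s0, e0 in seen.setdefault((w.side, w.joint), []):
                if w.start_pct < e0 and s0 < w.end_pct:
                    raise ValueError("pause windows overlap for one (side, joint)")
            seen[(w.side, w.joint)].append((w.start_pct, w.end_pct))

    def stance_end_pct(self, side: str) -> float:
        return 100.0 * (1.0 - self.swing_percentage[side])

    def replace(self, **overrides) -> "GaitProfile":
        return dataclasses.replace(self, **overrides)


def _per_side(sound: float, affected: float, affected_side: str) -> dict[str, float]:
    other = "right" if affected_side == "left" else "left"
    return {affected_side: affected, other: sound}


# Group means for self-selected walking.  Stride durations are
# back-computed from speed using representative stride lengths
# (healthy 1.10 m, stroke 0.60 m, amputee 1.00 m); amputee speed is
# not reported for the source cohorts and defaults to a typical
# transfemoral self-selected 0.70 m/s.
_STRIDE_LENGTH = {"healthy": 1.10, "stroke": 0.60, "amputee": 1.00}
_GROUP_SPEED = {"healthy": 0.92, "stroke": 0.18, "amputee": 0.70}


def make_profile(
    group_label: str,
    overrides: dict | None = None,
    affected_side: str = "left",
) -> GaitProfile:
    """Build the default :class:`GaitProfile` for one group.

    ``overrides`` may replace any :class:`GaitProfile` field; per-side
    fields may be given either as a mapping or as a single number
    applied to both sides.
    """
    if group_label not in GROUPS:
        raise ValueError(f"unknown group label {group_label!r}")
    if affected_side not in SIDES:
        raise ValueError(f"unknown side {affected_side!r}")
    speed = _GROUP_SPEED[group_label]
    stride = _STRIDE_LENGTH[group_label] / speed

    if group_label == "healthy":
        prof = GaitProfile(
            group_label="healthy",
            side_roles={s: "sound" for s in SIDES},
            speed=speed,
            stride_duration=stride,
            swing_percentage={s: 0.53 for s in SIDES},
            rom_hip={s: 62.33 for s in SIDES},
            rom_knee={s: 44.38 for s in SIDES},
        )
    elif group_label == "stroke":
        prof = GaitProfile(
            group_label="stroke",
            side_roles=_per_side("sound", "affected", affected_side),
            speed=speed,
            stride_duration=stride,
            swing_percentage=_per_side(0.70, 0.57, affected_side),
            rom_hip=_per_side(48.72, 41.42, affected_side),
            rom_knee=_per_side(39.37, 35.92, affected_side),
            pause_spec=(
                PauseWindow(affected_side, "knee", 18.0, 40.0),
                PauseWindow(affected_side, "knee", 80.0, 94.0),
                PauseWindow(_other(affected_side), "knee", 10.0, 24.0),
            ),
        )
    else:  # amputee
        prof = GaitProfile(
            group_label="amputee",
            side_roles=_per_side("sound", "affected", affected_side),
            speed=speed,
            stride_duration=stride,
            swing_percentage=_per_side(0.57, 0.54, affected_side),
            rom_hip=_per_side(59.52, 55.65, affected_side),
            rom_knee=_per_side(43.09, 42.80, affected_side),
            pause_spec=(
                PauseWindow(affected_side, "knee", 14.0, 42.0),
                PauseWindow(affected_side, "knee", 84.0, 94.0),
            ),
        )

    if overrides:
        fields = {f.name for f in dataclasses.fields(GaitProfile)}
        unknown = set(overrides) - fields
        if unknown:
            raise ValueError(f"unknown profile overrides: {sorted(unknown)}")
        fixed = {}
        for key, val in overrides.items():
            if key in ("swing_percentage", "rom_hip", "rom_knee") and np.isscalar(val):
                val = {s: float(val) for s in SIDES}
            if key == "pause_spec":
                val = tuple(PauseWindow(*w) for w in val)
            fixed[key] = val
        prof = prof.replace(**fixed)
    return prof


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def jitter_profile(profile: GaitProfile, subject_seed: int, sd: float = 0.05) -> GaitProfile:
    """Simulate inter-subject variability.

    Each continuous parameter is multiplied by an independent
    lognormal(0, ``sd``) factor drawn under ``subject_seed``; swing
    percentages are clipped to (0.2, 0.8).  Pause windows and the
    sampling setup are left untouched.
    """
    rng = np.random.default_rng(subject_seed)

    def jit() -> float:
        return float(np.exp(rng.normal(0.0, sd)))

    def jit_side(mapping: dict[str, float], clip: tuple[float, float] | None = None):
        out = {}
        for side in SIDES:
            v = mapping[side] * jit()
            if clip is not None:
                v = float(np.clip(v, *clip))
            out[side] = v
        return out

    return profile.replace(
        speed=profile.speed * jit(),
        stride_duration=profile.stride_duration * jit(),
        swing_percentage=jit_side(profile.swing_percentage, clip=(0.2, 0.8)),
        rom_hip=jit_side(profile.rom_hip),
        rom_knee=jit_side(profile.rom_knee),
    )
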