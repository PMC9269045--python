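"""Dataset assembly for interlimb and intralimb synergy estimation.

Three estimation tasks are supported:

``interlimb_hip`` / ``interlimb_knee``
    inputs are the contralateral limb's hip and knee angles plus their
    angular velocities (4 channels); the target is the estimated
    side's hip (resp. knee) angle.

``intralimb_knee``
    inputs are the ipsilateral thigh IMU channels — angular velocity
    plus 3-axis acceleration (4 channels); the target is the same
    side's knee angle.

Inputs are z-normalized per channel with statistics computed from the
training subjects only; the held-out subject is normalized with those
same statistics.  Targets stay in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TASKS = ("interlimb_hip", "interlimb_knee", "intralimb_knee")

CHANNEL_SETS = {
    "interlimb_hip": (
        ["contra_hip_deg", "contra_knee_deg", "contra_hip_dps", "contra_knee_dps"],
        "hip_deg",
    ),
    "interlimb_knee": (
        ["contra_hip_deg", "contra_knee_deg", "contra_hip_dps", "contra_knee_dps"],
        "knee_deg",
    ),
    "intralimb_knee": (
        ["thigh_gyro_dps", "thigh_acc_x", "thigh_acc_y", "thigh_acc_z"],
        "knee_deg",
    ),
}


@dataclass(frozen=True)
class ChannelSpec:
    """Input/target channel layout of one estimation task."""

    task: str
    input_channels: tuple[str, ...]
    target_channel: str

    @classmethod
    def for_task(cls, task: str) -> "ChannelSpec":
        if task not in CHANNEL_SETS:
            raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
        inputs, target = CHANNEL_SETS[task]
        return cls(task=task, input_channels=tuple(inputs), target_channel=target)

    def __post_init__(self) -> None:
        if self.target_channel in self.input_channels:
            raise ValueError("target channel must not appear among the inputs")


@dataclass
class SequenceDataset:
    """Per-subject input matrices and target series for one task."""

    spec: ChannelSpec
    inputs: dict[str, np.ndarray]  # subject -> (T, C)
    targets: dict[str, np.ndarray]  # subject -> (T,)
    sampling_rate: float
    norm_mean: np.ndarray | None = None  # per input channel
    norm_sd: np.ndarray | None = None
    normalized: bool = False

    @property
    def subjects(self) -> list[str]:
        return sorted(self.inputs)

    @property
    def n_channels(self) -> int:
        return len(self.spec.input_channels)

    def subset(self, subjects: list[str]) -> "SequenceDataset":
        return SequenceDataset(
            spec=self.spec,
            inputs={s: self.inputs[s] for s in subjects},
            targets={s: self.targets[s] for s in subjects},
            sampling_rate=self.sampling_rate,
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
            normalized=self.normalized,
        )

    def fit_normalization(self, training_subjects: list[str]) -> None:
        """Compute per-channel statistics from the given subjects only."""
        stack = np.concatenate([self.inputs[s] for s in training_subjects], axis=0)
        self.norm_mean = stack.mean(axis=0)
        sd = stack.std(axis=0)
        self.norm_sd = np.where(sd > 1e-12, sd, 1.0)

    def apply_normalization(self) -> None:
        """Z-normalize every subject's inputs with the stored statistics.

        Guarded: a second call is rejected rather than silently
        re-normalizing already normalized data.
        """
        if self.normalized:
            raise RuntimeError("dataset inputs are already normalized")
        if self.norm_mean is None or self.norm_sd is None:
            raise RuntimeError("call fit_normalization before apply_normalization")
        for s in self.inputs:
            self.inputs[s] = (self.inputs[s] - self.norm_mean) / self.norm_sd
        self.normalized = True


def _trial_channels(trial, side: str) -> dict[str, np.ndarray]:
    """Named channel bank for one side of a trial (velocities derived)."""
    fs = trial.sampling_rate
    hip = trial.angles[(side, "hip")]
    knee = trial.angles[(side, "knee")]
    return {
        "hip_deg": hip,
        "knee_deg": knee,
        "hip_dps": np.gradient(hip) * fs,
        "knee_dps": np.gradient(knee) * fs,
        "thigh_gyro_dps": trial.thigh_gyro[side],
        "thigh_acc_x": trial.thigh_acc[side][:, 0],
        "thigh_acc_y": trial.thigh_acc[side][:, 1],
        "thigh_acc_z": trial.thigh_acc[side][:, 2],
    }


def build_dataset(
    trials: dict[str, object],
    spec: ChannelSpec,
    target_side: str = "left",
    normalize: bool = False,
) -> SequenceDataset:
    """Assemble a :class:`SequenceDataset` from per-subject trials.

    ``target_side`` is the estimated limb; for interlimb tasks the
    inputs come from the opposite side.  Normalization is left to the
    evaluation loop by default so that statistics can exclude the
    held-out subject.
    """
    input_side = {"left": "right", "right": "left"}[target_side]
    inputs: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    fs = None
    for subject, trial in trials.items():
        fs = trial.sampling_rate
        if spec.task.startswith("interlimb"):
            bank = _trial_channels(trial, input_side)
            tgt_bank = _trial_channels(trial, target_side)
            cols = []
            for ch in spec.input_channels:
                key = ch.replace("contra_", "")
                if key not in bank:
                    raise KeyError(f"missing channel {ch!r} for subject {subject!r}")
                cols.append(bank[key])
            target = tgt_bank[spec.target_channel]
        else:
            bank = _trial_channels(trial, target_side)
            cols = []
            for ch in spec.input_channels:
                if ch not in bank:
                    raise KeyError(f"missing channel {ch!r} for subject {subject!r}")
                cols.append(bank[ch])
            target = bank[spec.target_channel]
        inputs[subject] = np.column_stack(cols)
        targets[subject] = np.asarray(target, dtype=float)
    ds = SequenceDataset(spec=spec, inputs=inputs, targets=targets, sampling_rate=float(fs))
    if normalize:
        ds.fit_normalization(ds.subjects)
        ds.apply_normalization()
    return ds


def nonlinear_interlimb_dataset(
    trials: dict[str, object],
    task: str = "interlimb_knee",
    target_side: str = "left",
    saturation_deg: float = 12.0,
    gain_depth: float = 0.6,
) -> SequenceDataset:
    """Interlimb dataset whose target carries a deliberately nonlinear coupling.

    The target is the contralateral angle of the task's target joint
    passed through a soft (tanh) saturation with scale
    ``saturation_deg`` and multiplied by a phase-dependent gain
    ``1 + gain_depth * sin(2*pi*phase)``, so no purely linear map from
    the inputs can reproduce it exactly.
    """
    spec = ChannelSpec.for_task(task)
    ds = build_dataset(trials, spec, target_side=target_side)
    input_side = {"left": "right", "right": "left"}[target_side]
    joint = spec.target_channel.replace("_deg", "")
    for subject, trial in trials.items():
        base = trial.angles[(input_side, joint)]
        spc = trial.samples_per_cycle
        phase = (np.arange(len(base)) % spc) / spc
        amp = np.ptp(base) / 2.0
        sat = amp * np.tanh((base - base.mean()) / saturation_deg)
        ds.targets[subject] = sat * (1.0 + gain_depth * np.sin(2.0 * np.pi * phase))
    return ds
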