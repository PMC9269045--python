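"""Delimited-text interchange for trials, profiles and result tables.

The canonical motion dialect is a long-format CSV with columns
``time_s, side, channel, value`` where channel is one of ``hip_deg,
knee_deg, thigh_gyro_dps, thigh_acc_x, thigh_acc_y, thigh_acc_z``,
plus a companion events table ``side, event, sample_index`` (event in
HS/TO).  Angles are degrees; a table declaring radians is converted on
import and the conversion is logged.  Result tables are CSV with a
JSON metadata sidecar carrying units, the master seed and a config
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiles import GaitProfile, PauseWindow, SIDES
from .synthetic import SyntheticTrial

log = logging.getLogger("gaitsynergy")

MOTION_CHANNELS = (
    "hip_deg",
    "knee_deg",
    "thigh_gyro_dps",
    "thigh_acc_x",
    "thigh_acc_y",
    "thigh_acc_z",
)


def write_trial(trial: SyntheticTrial, path: str | Path) -> None:
    """Write a trial as long-format CSV plus an events companion table."""
    path = Path(path)
    n = trial.n_samples
    t = np.arange(n) / trial.sampling_rate
    frames = []
    for side in SIDES:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.tile(t, 6),
                    "side": side,
                    "channel": np.repeat(list(MOTION_CHANNELS), n),
                    "value": np.concatenate(
                        [
                            trial.angles[(side, "hip")],
                            trial.angles[(side, "knee")],
                            trial.thigh_gyro[side],
                            trial.thigh_acc[side][:, 0],
                            trial.thigh_acc[side][:, 1],
                            trial.thigh_acc[side][:, 2],
                        ]
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    ev_rows = []
    for side in SIDES:
        hs, to = trial.events(side)
        ev_rows.extend({"side": side, "event": "HS", "sample_index": int(i)} for i in hs)
        ev_rows.extend({"side": side, "event": "TO", "sample_index": int(i)} for i in to)
    pd.DataFrame(ev_rows).sort_values(["side", "sample_index"]).to_csv(
        path.with_suffix(".events.csv"), index=False
    )


def import_motion_table(
    path: str | Path,
    sampling_rate: float,
    angle_unit: str = "deg",
    events_path: str | Path | None = None,
) -> dict:
    """Read a long-format motion table into per-(side, channel) arrays.

    Returns a dict with keys ``angles``, ``thigh_gyro``, ``thigh_acc``,
    ``heel_strikes``, ``toe_offs``, ``sampling_rate``.  Radian-declared
    angles are converted to degrees (and the conversion logged).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "side", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"motion table must have columns {sorted(required)}")
    unknown = set(df.channel.unique()) - set(MOTION_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels in motion table: {sorted(unknown)}")
    factor = 1.0
    if angle_unit == "rad":
        factor = 180.0 / np.pi
        log.info("converting imported angles from radians to degrees")
    elif angle_unit != "deg":
        raise ValueError(f"unknown angle unit {angle_unit!r}")
    out = {"angles": {}, "thigh_gyro": {}, "thigh_acc": {}, "sampling_rate": sampling_rate}
    for side, sub in df.groupby("side"):
        piv = {ch: g.sort_values("time_s").value.to_numpy() for ch, g in sub.groupby("channel")}
        for joint in ("hip", "knee"):
            key = f"{joint}_deg"
            if key not in piv:
                raise ValueError(f"channel missing for side {side!r}: {key!r}")
            out["angles"][(side, joint)] = piv[key] * factor
        if "thigh_gyro_dps" in piv:
            out["thigh_gyro"][side] = piv["thigh_gyro_dps"] * factor
        acc_keys = [f"thigh_acc_{ax}" for ax in "xyz"]
        if all(k in piv for k in acc_keys):
            out["thigh_acc"][side] = np.column_stack([piv[k] for k in acc_keys])
    out["heel_strikes"], out["toe_offs"] = {}, {}
    ev_path = Path(events_path) if events_path else path.with_suffix(".events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        for side, sub in ev.groupby("side"):
            out["heel_strikes"][side] = np.sort(
                sub[sub.event == "HS"].sample_index.to_numpy(int)
            )
            out["toe_offs"][side] = np.sort(sub[sub.event == "TO"].sample_index.to_numpy(int))
    return out


def profile_to_yaml(profile: GaitProfile, path: str | Path) -> None:
    doc = dataclasses.asdict(profile)
    doc["pause_spec"] = [list(w) for w in profile.pause_spec]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def profile_from_yaml(path: str | Path) -> GaitProfile:
    doc = yaml.safe_load(Path(path).read_text())
    doc["pause_spec"] = tuple(PauseWindow(*w) for w in doc.get("pause_spec", []))
    return GaitProfile(**doc)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[
        :12
    ]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a result table with a JSON metadata sidecar (units, seed, hash)."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = dict(meta or {})
    sidecar.setdefault("columns", list(df.columns))
    sidecar.setdefault("n_rows", int(len(df)))
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))
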