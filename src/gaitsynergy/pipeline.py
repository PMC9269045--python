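"""End-to-end analysis stages: trials -> cycles -> CRP/DI tables -> determinants.

These helpers bind the preprocessing, CRP and decomposition modules
into the two studies the package supports: quantifying interlimb and
intralimb synergy in patient cohorts (against a healthy reference) and
preparing the feature tables for the determinant analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crp import CRPSeries, crp_compare, mean_crp_curve, subject_crp_profile
from .decomposition import trial_di
from .preprocessing import (
    JointTrajectory,
    NormalizedCycle,
    fit_sinusoid_sum,
    normalize_cycle,
    representative_cycle,
)
from .profiles import SIDES
from .synthetic import SyntheticTrial


def trial_cycles(
    trial: SyntheticTrial, side: str, smooth_order: int | None = None
) -> list[tuple[NormalizedCycle, NormalizedCycle]]:
    """Normalized (hip, knee) cycle pairs of one trial side.

    Cycles are cut at the trial's heel strikes; the toe-off inside each
    interval sets the stance/swing boundary.
    """
    hs, to = trial.events(side)
    pairs = []
    for a, b in zip(hs[:-1], hs[1:]):
        inside = to[(to > a) & (to < b)]
        if len(inside) != 1:
            continue
        toe = int(inside[0])
        cyc = {}
        for joint in ("hip", "knee"):
            traj = JointTrajectory(
                trial.angles[(side, joint)], trial.sampling_rate, joint=joint, side=side
            )
            c = normalize_cycle(traj, (int(a), int(b)), toe)
            if smooth_order is not None:
                _, c = fit_sinusoid_sum(c, smooth_order)
            cyc[joint] = c
        pairs.append((cyc["hip"], cyc["knee"]))
    return pairs


def representative_cycles(
    trial: SyntheticTrial, smooth_order: int | None = 6, frame: str = "own"
) -> dict[tuple[str, str], NormalizedCycle]:
    """One representative normalized cycle per (side, joint).

    ``frame="own"`` cuts each side at its own heel strikes (the frame
    for intralimb coordination).  ``frame="reference"`` cuts *both*
    sides at the reference (right/sound) side's heel strikes, the
    common time base interlimb CRP needs — in that frame a half-cycle
    contralateral shift shows up as an antiphase (180 degree) relation
    rather than cancelling out.
    """
    out = {}
    if frame == "own":
        for side in SIDES:
            pairs = trial_cycles(trial, side, smooth_order=smooth_order)
            if not pairs:
                raise ValueError(f"no complete cycles for side {side!r}")
            out[(side, "hip")] = representative_cycle([h for h, _ in pairs])
            out[(side, "knee")] = representative_cycle([k for _, k in pairs])
        return out
    if frame != "reference":
        raise ValueError(f"unknown frame {frame!r}")
    ref = "right"
    hs, to = trial.events(ref)
    for side in SIDES:
        collected: dict[str, list[NormalizedCycle]] = {"hip": [], "knee": []}
        for a, b in zip(hs[:-1], hs[1:]):
            inside = to[(to > a) & (to < b)]
            if len(inside) != 1:
                continue
            toe = int(inside[0])
            for joint in ("hip", "knee"):
                traj = JointTrajectory(
                    trial.angles[(side, joint)], trial.sampling_rate, joint=joint, side=side
                )
                c = normalize_cycle(traj, (int(a), int(b)), toe)
                if smooth_order is not None:
                    _, c = fit_sinusoid_sum(c, smooth_order)
                collected[joint].append(c)
        for joint in ("hip", "knee"):
            if not collected[joint]:
                raise ValueError("no complete reference-frame cycles")
            out[(side, joint)] = representative_cycle(collected[joint])
    return out


def healthy_reference(
    cohort: dict[str, SyntheticTrial], smooth_order: int | None = 6
) -> dict[str, crp_mod.CRPSeries]:
    """Group-mean CRP curves of a healthy cohort.

    Returns circular-mean reference curves keyed ``intralimb`` (hip–knee,
    pooled over sides) and ``interlimb`` (the summary interlimb series).
    """
    intra, inter = [], []
    for trial in cohort.values():
        own = representative_cycles(trial, smooth_order, frame="own")
        ref_frame = representative_cycles(trial, smooth_order, frame="reference")
        intra.extend(subject_crp_profile(own, "intralimb"))
        inter.append(subject_crp_profile(ref_frame, "interlimb")[-1])
    return {
        "intralimb": mean_crp_curve(intra),
        "interlimb": mean_crp_curve(inter),
    }


def cohort_crp_table(
    cohort: dict[str, SyntheticTrial],
    reference: dict[str, crp_mod.CRPSeries],
    smooth_order: int | None = 6,
) -> pd.DataFrame:
    """Tidy CRP deviation table: one row per subject/pairing/side/window.

    The deviation is the wrapped RMSE (and PCC) of the subject's CRP
    curve against the healthy-group reference curve for that pairing.
    """
    rows = []
    for subject, trial in cohort.items():
        own = representative_cycles(trial, smooth_order, frame="own")
        ref_frame = representative_cycles(trial, smooth_order, frame="reference")
        intra = subject_crp_profile(own, "intralimb")
        inter = subject_crp_profile(ref_frame, "interlimb")[-1]
        entries = [("intralimb", s.pair_label[0].split("_")[0], s) for s in intra]
        entries.append(("interlimb", "both", inter))
        for pairing, side, series in entries:
            for window in ("whole", "stance", "swing"):
                cmpres = crp_compare(series, reference[pairing], window)
                rows.append(
                    {
                        "subject": subject,
                        "group": trial.profile.group_label,
                        "pairing": pairing,
                        "side": side,
                        "role": trial.profile.side_roles.get(side, "both"),
                        "window": window,
                        "rmse_deg": cmpres.rmse,
                        "pcc": cmpres.pcc,
                    }
                )
    return pd.DataFrame(rows)


def cohort_di_table(cohort: dict[str, SyntheticTrial], smooth_order: int | None = 12) -> pd.DataFrame:
    """Tidy hip–knee DI table: one row per subject and side."""
    rows = []
    for subject, trial in cohort.items():
        for side in SIDES:
            di = trial_di(trial, side, smooth_order=smooth_order)
            rows.append(
                {
                    "subject": subject,
                    "group": trial.profile.group_label,
                    "side": side,
                    "role": trial.profile.side_roles[side],
                    "di_whole": di.di_whole,
                    "di_stance": di.di_stance,
                    "di_swing": di.di_swing,
                    "threshold_dps": di.threshold,
                }
            )
    return pd.DataFrame(rows)


def build_feature_table(
    cohort: dict[str, SyntheticTrial],
    reference: dict[str, crp_mod.CRPSeries],
    pairing: str = "intralimb",
    window: str = "whole",
    smooth_order: int | None = 6,
) -> pd.DataFrame:
    """Subject-side feature table for the determinant analysis.

    The response column ``crp_rmse`` is the CRP deviation against the
    healthy reference for the requested pairing and window; predictors
    are the per-side decomposition indices plus the realized profile
    kinematics.
    """
    crp_table = cohort_crp_table(cohort, reference, smooth_order)
    di_table = cohort_di_table(cohort)
    sel = crp_table[(crp_table.pairing == pairing) & (crp_table.window == window)]
    rows = []
    for _, r in sel.iterrows():
        trial = cohort[r.subject]
        prof = trial.profile
        sides = SIDES if r.side == "both" else (r.side,)
        for side in sides:
            di = di_table[(di_table.subject == r.subject) & (di_table.side == side)].iloc[0]
            rows.append(
                {
                    "subject": r.subject,
                    "side": side,
                    "group": prof.group_label,
                    "crp_rmse": r.rmse_deg,
                    "di_stance": di.di_stance,
                    "di_swing": di.di_swing,
                    "rom_hip": prof.rom_hip[side],
                    "rom_knee": prof.rom_knee[side],
                    "swing_percentage": prof.swing_percentage[side],
                    "speed": prof.speed,
                }
            )
    return pd.DataFrame(rows)
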