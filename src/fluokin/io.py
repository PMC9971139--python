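"""Bit-stable CSV readers and writers for tracks, features and scores.

Track CSV dialect: columns ``t_s, x_mm, y_mm, z_mm, mode, event`` with
mode 0 = white light / 1 = firefly and event in {none, open_correct,
open_wrong}; mandatory header, decimal point, UTF-8.  Validation errors name
the offending column or line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import EVENT_LABELS, KinematicFeatures, Track

TRACK_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "mode", "event"]
FEATURE_COLUMNS = [
    "exercise_id", "s_m", "t_task_s", "t_firefly_s", "v_mps", "a_mps2",
    "J", "n_J_extr", "ST", "Cr", "AD", "HE", "sbr_min",
]
SCORE_COLUMNS = ["exercise_id", "Dx", "DM", "F", "P_Dx", "P_DM", "PS", "proficient"]


def write_track(track: Track, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_s": track.t_s, "x_mm": track.x_mm, "y_mm": track.y_mm,
        "z_mm": track.z_mm, "mode": track.mode, "event": track.event,
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_track(path: str | Path) -> Track:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"track file not found: {path}") from None
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track column(s): {missing}")
    for col in ("t_s", "x_mm", "y_mm", "z_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2  # + header + 1-based
            raise ValueError(f"{path}: non-numeric value in '{col}' at line {line}")
        df[col] = vals
    dt = np.diff(df["t_s"].to_numpy())
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise ValueError(f"{path}: timestamps not strictly increasing at line {line}")
    bad = ~df["event"].isin(EVENT_LABELS)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: unknown event label at line {line}")
    return Track(
        t_s=df["t_s"].to_numpy(), x_mm=df["x_mm"].to_numpy(),
        y_mm=df["y_mm"].to_numpy(), z_mm=df["z_mm"].to_numpy(),
        mode=df["mode"].to_numpy(int), event=df["event"].to_numpy(object),
    )


def write_features(features: Sequence[KinematicFeatures] | pd.DataFrame,
                   path: str | Path) -> None:
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame([vars(f) for f in features])
    features[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s): {missing}")
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing score column(s): {missing}")
    return df
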