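"""Head-movement markers from per-frame pose.

The tracker reports head translation (Tx, Ty, Tz, tracker units) and rotation
(Rx, Ry, Rz, radians, Euler) per frame.  Three kinematic markers summarize a
response:

* *head movement mean* — mean framewise displacement (Euclidean norm of the
  translation difference between consecutive valid frames);
* *head movement standard deviation* — sample SD of those displacements;
* *head pose change mean* — mean norm of the framewise Euler-angle difference.

Frames removed by the quality gate break the chain: no displacement is
computed across a gap (consecutive frame indices only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRANSLATION_COLS = ("pose_Tx", "pose_Ty", "pose_Tz")
ROTATION_COLS = ("pose_Rx", "pose_Ry", "pose_Rz")

MOVEMENT_MARKERS = ("head_movement_mean", "head_movement_std", "head_pose_change_mean")


def _consecutive_diffs(frames: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    """Norms of per-frame differences, skipping pairs across frame-index gaps."""
    for c in cols:
        if c not in frames.columns:
            raise ValueError(f"pose table lacks required column '{c}'")
    if len(frames) < 2:
        return np.empty(0)
    xyz = frames.loc[:, list(cols)].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("pose values must be finite")
    d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    if "frame" in frames.columns:
        idx = frames["frame"].to_numpy()
        contiguous = np.diff(idx) == 1
        d = d[contiguous]
    return d


def framewise_displacement(frames: pd.DataFrame) -> np.ndarray:
    """Per-frame head displacement series (tracker units/frame)."""
    return _consecutive_diffs(frames, TRANSLATION_COLS)


def head_movement_stats(displacements: np.ndarray) -> tuple[float, float]:
    """(mean, sample SD) of a displacement series; NaN when undefined."""
    d = np.asarray(displacements, dtype=float)
    if d.size == 0:
        return float("nan"), float("nan")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size >= 2 else float("nan")
    return mean, sd


def head_pose_change(frames: pd.DataFrame) -> float:
    """Mean framewise angular change (radians/frame); NaN with <2 frames."""
    diffs = _consecutive_diffs(frames, ROTATION_COLS)
    if diffs.size == 0:
        return float("nan")
    return float(diffs.mean())


def movement_marker_row(frames: pd.DataFrame, per_second: bool = False, fps: float = 30.0) -> dict[str, float]:
    """All three movement markers for one response's (already gated) pose table.

    ``per_second=True`` rescales displacement markers to units/second for
    mixed-frame-rate data; the default reports raw units/frame.
    """
    d = framewise_displacement(frames)
    mean, sd = head_movement_stats(d)
    ang = head_pose_change(frames)
    scale = fps if per_second else 1.0
    return {
        "head_movement_mean": mean * scale,
        "head_movement_std": sd * scale,
        "head_pose_change_mean": ang * scale,
    }
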