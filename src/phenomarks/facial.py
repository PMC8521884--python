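"""Facial markers from per-frame action-unit (AU) tracking output.

The tracker emits, per video frame, a binary presence flag ``AUxx_c`` and a
0-5 intensity ``AUxx_r`` for each FACS action unit, plus tracking quality
fields.  Thirteen facial markers are derived per response:

* six *emotion counts* — the fraction of valid frames whose most probable
  basic emotion (by AU-prototype match) is that emotion;
* six *emotion intensities* — the mean over valid frames of the emotion's
  per-frame intensity (mean of its constituent AU intensities);
* *overall expressivity* — mean over frames of the per-frame sum of the six
  emotion intensities.

Emotion prototypes follow the EMFACS/Ekman basic-emotion AU sets and are
swappable via :data:`DEFAULT_EMOTION_MAP`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: EMFACS-style AU prototypes for the six basic emotions.
DEFAULT_EMOTION_MAP: dict[str, frozenset[int]] = {
    "happiness": frozenset({6, 12}),
    "sadness": frozenset({1, 4, 15}),
    "surprise": frozenset({1, 2, 5, 26}),
    "fear": frozenset({1, 2, 4, 5, 7, 20, 26}),
    "anger": frozenset({4, 5, 7, 23}),
    "disgust": frozenset({9, 15}),
}

#: Fixed tie-break / reporting order for emotions.
EMOTION_ORDER = ("happiness", "sadness", "surprise", "fear", "anger", "disgust")

#: A frame is labeled with an emotion only if at least this fraction of the
#: emotion's constituent AUs are present.
MATCH_THRESHOLD = 0.5

#: Frames below this tracker confidence are discarded.
MIN_CONFIDENCE = 0.70

FACIAL_MARKERS = tuple(
    [f"{e}_count" for e in EMOTION_ORDER]
    + [f"{e}_intensity" for e in EMOTION_ORDER]
    + ["overall_expressivity"]
)


def au_column(au: int, kind: str) -> str:
    """OpenFace-dialect AU column name, e.g. ``AU01_r`` / ``AU12_c``."""
    if kind not in ("r", "c"):
        raise ValueError("kind must be 'r' (intensity) or 'c' (presence)")
    return f"AU{au:02d}_{kind}"


def filter_valid_frames(frames: pd.DataFrame, min_confidence: float = MIN_CONFIDENCE) -> pd.DataFrame:
    """Keep frames with ``success == 1`` and ``confidence >= min_confidence``."""
    for col in ("success", "confidence"):
        if col not in frames.columns:
            raise ValueError(f"frame table lacks required column '{col}'")
    mask = (frames["success"] == 1) & (frames["confidence"] >= min_confidence)
    return frames.loc[mask]


def _emotion_arrays(
    frames: pd.DataFrame, emotion_map: Mapping[str, frozenset[int]]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-frame (match, intensity) arrays, shape (n_frames, n_emotions)."""
    emotions = [e for e in EMOTION_ORDER if e in emotion_map]
    extra = [e for e in emotion_map if e not in EMOTION_ORDER]
    emotions += sorted(extra)
    match = np.empty((len(frames), len(emotions)))
    intensity = np.empty_like(match)
    for j, emo in enumerate(emotions):
        aus = sorted(emotion_map[emo])
        pres_cols = [au_column(a, "c") for a in aus]
        int_cols = [au_column(a, "r") for a in aus]
        missing = [c for c in pres_cols + int_cols if c not in frames.columns]
        if missing:
            raise ValueError(f"frame table lacks AU columns {missing} for emotion '{emo}'")
        match[:, j] = frames[pres_cols].to_numpy(dtype=float).mean(axis=1)
        intensity[:, j] = frames[int_cols].to_numpy(dtype=float).mean(axis=1)
    return match, intensity, emotions


def frame_emotion_labels(
    frames: pd.DataFrame,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
    match_threshold: float = MATCH_THRESHOLD,
) -> pd.Series:
    """Most-probable emotion per frame, or ``None`` when no prototype matches.

    The winner is the emotion with the highest fraction of its constituent AUs
    present, required to reach ``match_threshold``.  Ties break by higher
    per-frame intensity, then by the fixed order :data:`EMOTION_ORDER`.
    """
    match, intensity, emotions = _emotion_arrays(frames, emotion_map)
    n = match.shape[0]
    best_j = np.full(n, -1)
    best_match = np.full(n, -np.inf)
    best_int = np.full(n, -np.inf)
    # earlier emotions in EMOTION_ORDER win exact (match, intensity) ties
    for j in range(len(emotions)):
        eligible = match[:, j] >= match_threshold
        better = eligible & (
            (match[:, j] > best_match)
            | ((match[:, j] == best_match) & (intensity[:, j] > best_int))
        )
        best_j[better] = j
        best_match[better] = match[better, j]
        best_int[better] = intensity[better, j]
    labels = [emotions[j] if j >= 0 else None for j in best_j]
    return pd.Series(labels, index=frames.index, dtype=object)


def emotion_counts(
    frames: pd.DataFrame,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
    match_threshold: float = MATCH_THRESHOLD,
) -> dict[str, float]:
    """Fraction of valid frames labeled with each emotion (plus ``none``).

    The six counts and the ``none`` fraction partition the frames and sum to 1.
    Returns NaN for every emotion on an empty table (missing marker, not zero).
    """
    emotions = list(emotion_map)
    if len(frames) == 0:
        return {e: float("nan") for e in emotions} | {"none": float("nan")}
    labels = frame_emotion_labels(frames, emotion_map, match_threshold)
    n = len(frames)
    out = {e: float((labels == e).sum()) / n for e in emotions}
    out["none"] = float(labels.isna().sum()) / n
    return out


def emotion_intensities(
    frames: pd.DataFrame,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
) -> dict[str, float]:
    """Mean per-frame intensity of each emotion over valid frames.

    Per-frame emotion intensity is the mean of the constituent AU intensities
    (0-5 scale).  NaN on an empty table.
    """
    emotions = list(emotion_map)
    if len(frames) == 0:
        return {e: float("nan") for e in emotions}
    _, intensity, order = _emotion_arrays(frames, emotion_map)
    means = intensity.mean(axis=0)
    return {e: float(means[order.index(e)]) for e in emotions}


def overall_expressivity(
    frames: pd.DataFrame,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
) -> float:
    """Composite facial activity: per-frame sum of emotion intensities, averaged.

    Bounded by [0, 5 x n_emotions].  NaN on an empty table.
    """
    if len(frames) == 0:
        return float("nan")
    _, intensity, _ = _emotion_arrays(frames, emotion_map)
    return float(intensity.sum(axis=1).mean())


def overall_expressivity_au(frames: pd.DataFrame, au_ids: Sequence[int] | None = None) -> float:
    """Alternative composite: mean over frames of the mean raw AU intensity.

    Provided as a robustness variant; the emotion-sum composite
    (:func:`overall_expressivity`) is the default marker.
    """
    if len(frames) == 0:
        return float("nan")
    if au_ids is None:
        cols = [c for c in frames.columns if c.startswith("AU") and c.endswith("_r")]
    else:
        cols = [au_column(a, "r") for a in au_ids]
    if not cols:
        raise ValueError("no AU intensity columns found")
    return float(frames[cols].to_numpy(dtype=float).mean())


def facial_marker_row(
    frames: pd.DataFrame,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
    min_confidence: float = MIN_CONFIDENCE,
) -> dict[str, float]:
    """All 13 facial markers for one response's frame table.

    Applies the frame quality gate first; if no frame survives, every marker
    is NaN (missing), never zero.
    """
    valid = filter_valid_frames(frames, min_confidence)
    counts = emotion_counts(valid, emotion_map)
    intensities = emotion_intensities(valid, emotion_map)
    row = {f"{e}_count": counts[e] for e in emotion_map}
    row.update({f"{e}_intensity": intensities[e] for e in emotion_map})
    row["overall_expressivity"] = overall_expressivity(valid, emotion_map)
    return row
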