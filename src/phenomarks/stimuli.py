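"""Affective stimulus pipeline: valence normalization, classification, sequencing.

Assessment stimuli are drawn from a normatively rated image pool (OASIS-style:
each image carries a population-mean valence score). Scores are z-scored over
the pool and images are classified as negative / neutral / positive with buffer
zones in between so the classes are well separated. Each remote assessment
presents 13 images in the fixed pattern N P N X N P N X N P N X N (N neutral,
P positive, X negative), and no image is ever repeated for a subject across
the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed neutral band: |z| <= NEUTRAL_BAND is neutral.
NEUTRAL_BAND = 0.5
#: Outer thresholds (inclusive): z >= +OUTER positive, z <= -OUTER negative.
#: The source protocol prints the negative rule without a sign; it is read as
#: z <= -1.5 by symmetry with the positive rule.  See docs/methods.md.
OUTER_THRESHOLD = 1.5

#: Minimum speaking time per image for a valid response, seconds.
MIN_SPEECH_SECONDS = 10.0

#: Position pattern of one assessment sequence (13 items).
SEQUENCE_PATTERN = "NPNXNPNXNPNXN"

VALENCE_CLASSES = ("negative", "neutral", "positive", "buffer")


class PoolExhaustedError(RuntimeError):
    """Raised when a valence class has too few unused images left."""

    def __init__(self, valence_class: str, needed: int, available: int):
        self.valence_class = valence_class
        super().__init__(
            f"stimulus pool exhausted for class '{valence_class}': "
            f"need {needed} unused images, only {available} available"
        )


def zscore_valences(raw_scores: Sequence[float]) -> np.ndarray:
    """Standardize raw valence means to z-scores (population-SD convention).

    Raises ``ValueError`` on fewer than two scores or zero variance.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two valence scores to standardize")
    if not np.all(np.isfinite(x)):
        raise ValueError("valence scores must be finite")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("valence scores are constant; z-scores undefined")
    return (x - x.mean()) / sd


def classify_valence(
    z: float,
    neutral_band: float = NEUTRAL_BAND,
    outer_threshold: float = OUTER_THRESHOLD,
) -> str:
    """Classify a z-scored valence into negative/neutral/positive/buffer.

    The neutral band is closed (``|z| <= neutral_band``); the outer thresholds
    are inclusive (``z >= outer_threshold`` positive, ``z <= -outer_threshold``
    negative).  Scores between the bands fall in the excluded ``buffer`` zone.
    """
    if not math.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z!r}")
    if abs(z) <= neutral_band:
        return "neutral"
    if z >= outer_threshold:
        return "positive"
    if z <= -outer_threshold:
        return "negative"
    return "buffer"


def build_pool(image_ids: Sequence[str], raw_valences: Sequence[float]) -> pd.DataFrame:
    """Build a stimulus pool table with z-scores and valence classes.

    Returns a DataFrame with columns ``image_id, raw_valence, z_valence,
    valence_class``.
    """
    if len(image_ids) != len(raw_valences):
        raise ValueError("image_ids and raw_valences must have equal length")
    if len(set(image_ids)) != len(image_ids):
        raise ValueError("image_ids must be unique")
    z = zscore_valences(raw_valences)
    return pd.DataFrame(
        {
            "image_id": list(image_ids),
            "raw_valence": np.asarray(raw_valences, dtype=float),
            "z_valence": z,
            "valence_class": [classify_valence(v) for v in z],
        }
    )


@dataclass
class AssessmentSequence:
    """One assessment's ordered stimulus list.

    13 items: 7 neutral, 3 positive, 3 negative, starting and ending neutral,
    with no positive image adjacent to a negative one.
    """

    subject_id: str
    study_day: int
    items: list[tuple[int, str, str]] = field(default_factory=list)
    # items: (position, image_id, valence_class)

    def image_ids(self) -> list[str]:
        return [img for _, img, _ in self.items]

    def classes(self) -> list[str]:
        return [c for _, _, c in self.items]

    def validate(self) -> None:
        classes = self.classes()
        if len(self.items) != 13:
            raise ValueError(f"sequence must have 13 items, has {len(self.items)}")
        from collections import Counter

        counts = Counter(classes)
        if counts.get("neutral") != 7 or counts.get("positive") != 3 or counts.get("negative") != 3:
            raise ValueError(f"bad composition: {dict(counts)}")
        if classes[0] != "neutral" or classes[-1] != "neutral":
            raise ValueError("sequence must start and end with a neutral image")
        for a, b in zip(classes, classes[1:]):
            if {a, b} == {"positive", "negative"}:
                raise ValueError("positive and negative images must not be adjacent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.items, columns=["position", "image_id", "valence_class"]
        ).assign(subject_id=self.subject_id, study_day=self.study_day)


_PATTERN_CLASS = {"N": "neutral", "P": "positive", "X": "negative"}


def build_sequence(
    pool: pd.DataFrame,
    history: set[str],
    rng: np.random.Generator,
    subject_id: str = "",
    study_day: int = 0,
) -> AssessmentSequence:
    """Assemble one 13-image assessment sequence from unused pool images.

    Images are chosen uniformly at random within each valence class, excluding
    any id in ``history``.  The caller owns ``history`` and should update it
    with the returned sequence's ids to enforce the study-wide no-repeat rule.

    Raises :class:`PoolExhaustedError` naming the depleted class if fewer
    unused images remain than the pattern requires.
    """
    needed = {"neutral": 7, "positive": 3, "negative": 3}
    picks: dict[str, list[str]] = {}
    for cls, n in needed.items():
        unused = pool.loc[
            (pool["valence_class"] == cls) & ~pool["image_id"].isin(history), "image_id"
        ].to_numpy()
        if unused.size < n:
            raise PoolExhaustedError(cls, n, int(unused.size))
        picks[cls] = list(rng.choice(unused, size=n, replace=False))

    seq = AssessmentSequence(subject_id=subject_id, study_day=study_day)
    for pos, sym in enumerate(SEQUENCE_PATTERN):
        cls = _PATTERN_CLASS[sym]
        seq.items.append((pos, picks[cls].pop(), cls))
    seq.validate()
    return seq


def validate_response(speech_duration_s: float, min_seconds: float = MIN_SPEECH_SECONDS) -> bool:
    """A response is valid iff the subject spoke for at least ``min_seconds``."""
    if speech_duration_s < 0:
        raise ValueError("speech duration cannot be negative")
    return speech_duration_s >= min_seconds
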