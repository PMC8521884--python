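"""Voice activity detection and the voice-percentage marker.

A response recording is segmented into speech and non-speech by a windowed
log-energy detector with Praat-convention defaults: 10 ms analysis windows,
a dynamic threshold 25 dB below the loudest window, silent gaps shorter than
0.3 s bridged, and sounding runs shorter than 0.1 s discarded.  The marker is
the fraction of the recording spent speaking (*voice percentage*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Analysis window length, seconds.
WINDOW_S = 0.010
#: Dynamic threshold: window counts as sounding if its energy is within this
#: many dB of the loudest window.
DYNAMIC_RANGE_DB = 25.0
#: Silent gaps shorter than this are bridged into the surrounding speech.
MIN_SILENCE_S = 0.3
#: Sounding runs shorter than this are discarded.
MIN_SOUNDING_S = 0.1


@dataclass
class SpeechSegments:
    """Sorted, non-overlapping speech intervals within a recording."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    total_duration_s: float = 0.0

    def speech_time(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def validate(self) -> None:
        prev_end = 0.0
        for s, e in self.intervals:
            if not (0.0 <= s < e <= self.total_duration_s + 1e-9):
                raise ValueError(f"interval ({s}, {e}) outside [0, {self.total_duration_s}]")
            if s < prev_end - 1e-12:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = e


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_speech(
    samples: np.ndarray,
    sample_rate: float,
    window_s: float = WINDOW_S,
    dynamic_range_db: float = DYNAMIC_RANGE_DB,
    min_silence_s: float = MIN_SILENCE_S,
    min_sounding_s: float = MIN_SOUNDING_S,
) -> SpeechSegments:
    """Segment an amplitude series into speech intervals.

    The threshold is relative to the loudest window, so rescaling the signal
    by any positive constant leaves the segmentation unchanged.  A digitally
    silent signal yields zero segments.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty amplitude series")
    win = int(round(window_s * sample_rate))
    if x.size < win:
        raise ValueError(
            f"series shorter ({x.size} samples) than one analysis window ({win})"
        )
    duration = x.size / sample_rate

    n_win = x.size // win
    frames = x[: n_win * win].reshape(n_win, win)
    energy = (frames**2).mean(axis=1)

    peak = energy.max()
    if peak <= 0.0:
        return SpeechSegments([], duration)
    with np.errstate(divide="ignore"):
        energy_db = 10.0 * np.log10(np.where(energy > 0, energy, np.finfo(float).tiny))
    sounding = energy_db >= (10.0 * np.log10(peak) - dynamic_range_db)

    # bridge short silent gaps between sounding runs
    max_gap = int(round(min_silence_s / window_s))
    runs = _runs(sounding)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # discard too-short sounding runs
    min_run = int(round(min_sounding_s / window_s))
    kept = [(s, e) for s, e in merged if e - s >= min_run]

    intervals = [
        (s * window_s, min(e * window_s, duration)) for s, e in kept
    ]
    seg = SpeechSegments(intervals, duration)
    seg.validate()
    return seg


def voice_percentage(segments: SpeechSegments) -> float:
    """Speech time divided by total recording time, in [0, 1]."""
    if segments.total_duration_s <= 0:
        raise ValueError("total duration must be positive")
    frac = segments.speech_time() / segments.total_duration_s
    return float(min(max(frac, 0.0), 1.0))


def voice_marker(samples: np.ndarray, sample_rate: float, **detector_params) -> float:
    """Convenience: detect speech and return the voice-percentage marker."""
    return voice_percentage(detect_speech(samples, sample_rate, **detector_params))
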