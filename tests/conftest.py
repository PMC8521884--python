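import numpy as np
import pandas as pd
import pytest

from phenomarks.facial import DEFAULT_EMOTION_MAP, au_column
from phenomarks.synthetic import AU_IDS


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_frames(n_frames, au_intensity=None, confidence=0.99, success=1, fps=30.0):
    """Build a minimal OpenFace-dialect frame table.

    ``au_intensity``: dict AU id -> scalar or length-n array of intensities.
    Presence flags follow the generator's activation rule (intensity > 1).
    """
    df = pd.DataFrame(
        {
            "frame": np.arange(n_frames, dtype=int),
            "timestamp": np.arange(n_frames) / fps,
            "confidence": np.broadcast_to(confidence, n_frames).astype(float),
            "success": np.broadcast_to(success, n_frames).astype(int),
        }
    )
    au_intensity = au_intensity or {}
    for au in AU_IDS:
        vals = np.broadcast_to(au_intensity.get(au, 0.0), n_frames).astype(float)
        df[au_column(au, "r")] = vals
        df[au_column(au, "c")] = (vals > 1.0).astype(int)
    return df


def emotion_aus(emotion):
    return sorted(DEFAULT_EMOTION_MAP[emotion])


@pytest.fixture
def frames_factory():
    return make_frames
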