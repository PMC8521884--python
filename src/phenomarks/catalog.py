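"""The fixed catalog of the 17 digital markers and stimulus conditions."""

from .facial import FACIAL_MARKERS
from .movement import MOVEMENT_MARKERS

#: Canonical reporting order: 13 facial + 1 voice + 3 movement markers.
MARKER_CATALOG: tuple[str, ...] = FACIAL_MARKERS + ("voice_percentage",) + MOVEMENT_MARKERS

#: Stimulus valence conditions markers are analyzed under.
STIMULUS_CLASSES = ("neutral", "positive", "negative")

assert len(MARKER_CATALOG) == 17
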