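"""Canonical sleep-stage alphabet and label mappings.

Five-class staging over {W, N1, N2, SWS, REM}: the two deep NREM stages of
the older R&K convention (N3, N4) are merged into a single slow-wave-sleep
class, matching current AASM practice. Stages are encoded as fixed integers
so that fold plans, confusion matrices and model labels all agree.
"""

from __future__ import annotations

# Fixed integer encoding; confusion-matrix row order follows this.
W, N1, N2, SWS, REM = 0, 1, 2, 3, 4

STAGES: tuple[str, ...] = ("W", "N1", "N2", "SWS", "REM")
STAGE_TO_INT: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
INT_TO_STAGE: dict[int, str] = dict(enumerate(STAGES))

#: Raw scorer labels accepted from hypnogram files.
RAW_ALPHABET = frozenset({"W", "N1", "N2", "N3", "N4", "REM", "?", "MOVEMENT"})

#: R&K raw label -> canonical five-class label; "?"/MOVEMENT map to None (drop).
RAW_TO_CANONICAL: dict[str, str | None] = {
    "W": "W",
    "N1": "N1",
    "N2": "N2",
    "N3": "SWS",
    "N4": "SWS",
    "REM": "REM",
    "?": None,
    "MOVEMENT": None,
}

# Annotation texts as they appear in EDF+ hypnogram files.
ANNOTATION_TO_RAW: dict[str, str] = {
    "Sleep stage W": "W",
    "Sleep stage 1": "N1",
    "Sleep stage 2": "N2",
    "Sleep stage 3": "N3",
    "Sleep stage 4": "N4",
    "Sleep stage R": "REM",
    "Sleep stage ?": "?",
    "Movement time": "MOVEMENT",
    # bare labels (TSV dialect / already-normalised sources)
    "W": "W",
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
    "N4": "N4",
    "R": "REM",
    "REM": "REM",
    "SWS": "N3",  # canonical label written by the TSV dialect
    "?": "?",
    "MOVEMENT": "MOVEMENT",
}

RAW_TO_ANNOTATION: dict[str, str] = {
    "W": "Sleep stage W",
    "N1": "Sleep stage 1",
    "N2": "Sleep stage 2",
    "N3": "Sleep stage 3",
    "N4": "Sleep stage 4",
    "REM": "Sleep stage R",
    "?": "Sleep stage ?",
    "MOVEMENT": "Movement time",
}

EPOCH_SECONDS = 30
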