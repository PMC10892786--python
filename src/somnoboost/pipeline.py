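"""End-to-end helpers: files or simulated subjects → shifted feature matrix."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dataset import extract_features, shift_features
from .edf_io import Hypnogram, Recording, harmonise, read_hypnogram, read_recording
from .synthetic import simulate_subject

__all__ = [
    "build_feature_matrix",
    "features_from_files",
    "features_from_manifest",
    "simulate_feature_matrix",
]


def build_feature_matrix(
    pairs: list[tuple[Recording, Hypnogram]], shift: bool = True
) -> pd.DataFrame:
    """Concatenate per-recording feature matrices; optionally apply ±1 shifting."""
    frames = [extract_features(rec, hyp) for rec, hyp in pairs]
    matrix = pd.concat(frames, ignore_index=True)
    return shift_features(matrix) if shift else matrix


def features_from_files(
    psg_path: str | Path,
    hypnogram_path: str | Path,
    channel: str = "EEG Pz-Oz",
    wake_buffer: float = 30.0,
    shift: bool = True,
) -> pd.DataFrame:
    """Read one EDF pair, harmonise stages/trim wake, extract features."""
    rec = read_recording(psg_path, channel)
    raw = read_hypnogram(hypnogram_path)
    rec, hyp = harmonise(rec, raw, wake_buffer=wake_buffer)
    return build_feature_matrix([(rec, hyp)], shift=shift)


def features_from_manifest(
    manifest_path: str | Path,
    channel: str = "EEG Pz-Oz",
    wake_buffer: float = 30.0,
    shift: bool = True,
) -> pd.DataFrame:
    """Extract and pool features for every subject listed in a fixture manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    pairs = []
    for subj in manifest["subjects"]:
        rec = read_recording(root / subj["psg"], channel)
        raw = read_hypnogram(root / subj["hypnogram"])
        rec, hyp = harmonise(rec, raw, wake_buffer=wake_buffer)
        pairs.append((rec, hyp))
    return build_feature_matrix(pairs, shift=shift)


def simulate_feature_matrix(
    n_subjects: int,
    epochs_per_subject: int,
    preset: str = "easy",
    seed: int = 0,
    shift: bool = True,
) -> pd.DataFrame:
    """In-memory pipeline: simulate subjects and extract their features."""
    pairs = []
    for s in range(n_subjects):
        rec, hyp = simulate_subject(
            epochs_per_subject,
            preset=preset,
            seed=seed * 1000 + s,
            rec_id=f"SYN{s:02d}",
        )
        pairs.append((rec, hyp))
    return build_feature_matrix(pairs, shift=shift)
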