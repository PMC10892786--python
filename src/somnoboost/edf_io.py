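"""EDF input/output and hypnogram harmonisation.

Reading goes through :mod:`mne` (EDF signals, EDF+ annotations). Writing is
done by a small in-package EDF writer (16-bit signals; EDF+ TAL annotation
records) so synthetic fixtures can be produced without external tooling; the
round trip through mne's independent reader is exercised by the test suite.

Subject metadata (id, age, sex) travels in a small JSON sidecar next to the
signal file (``<stem>.meta.json``) — the EDF header's patient field is too
lossy for numeric age.

A plain TSV hypnogram dialect (``epoch_index<TAB>stage`` per line) is also
accepted and written, convenient for hand-made fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .stages import (
    ANNOTATION_TO_RAW,
    EPOCH_SECONDS,
    RAW_ALPHABET,
    RAW_TO_ANNOTATION,
    RAW_TO_CANONICAL,
    STAGES,
)

__all__ = [
    "Recording",
    "RawHypnogram",
    "Hypnogram",
    "read_recording",
    "read_hypnogram",
    "harmonise",
    "write_edf",
]


@dataclass
class Recording:
    """One channel of EEG with its sampling rate and subject metadata."""

    samples: np.ndarray  # amplitudes, µV
    rate: float  # Hz
    channel: str = "EEG Pz-Oz"
    age: float = 0.0  # years
    sex: str = "U"
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a nonempty 1-D vector")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass
class RawHypnogram:
    """Scorer annotations as (onset s, duration s, raw R&K label) entries."""

    entries: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for onset, dur, label in self.entries:
            if label not in RAW_ALPHABET:
                raise ValueError(f"unknown raw stage label {label!r}")
            if dur <= 0 or abs(dur % EPOCH_SECONDS) > 1e-9:
                raise ValueError(
                    f"entry at onset {onset}s has duration {dur}s, "
                    f"not a positive multiple of {EPOCH_SECONDS}s"
                )
            if onset < prev_onset:
                raise ValueError(f"onsets not non-decreasing at {onset}s")
            if onset < prev_end - 1e-9:
                raise ValueError(f"overlapping entry at onset {onset}s")
            prev_onset = onset
            prev_end = onset + dur

    def epoch_labels(self) -> list[str]:
        """Expand entries to one raw label per 30-s epoch."""
        labels: list[str] = []
        for onset, dur, label in self.entries:
            labels.extend([label] * int(round(dur / EPOCH_SECONDS)))
        return labels


@dataclass
class Hypnogram:
    """Canonical per-epoch stage labels, one per 30-s epoch."""

    stages: list[str]
    epoch_length: float = float(EPOCH_SECONDS)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"labels outside canonical alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)


# ---------------------------------------------------------------------------
# reading

def read_recording(path: str | Path, channel: str = "EEG Pz-Oz") -> Recording:
    """Read one named channel from an EDF file.

    Metadata (id, age, sex) is taken from a ``<stem>.meta.json`` sidecar when
    present, otherwise defaults are used with the file stem as the id.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel], units="uV")[0]
    meta = {"id": path.stem, "age": 0.0, "sex": "U"}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Recording(
        samples=data,
        rate=float(raw.info["sfreq"]),
        channel=channel,
        age=float(meta["age"]),
        sex=str(meta["sex"]),
        id=str(meta["id"]),
    )


def read_hypnogram(path: str | Path) -> RawHypnogram:
    """Read a hypnogram from an EDF+ annotation file or a TSV stage list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such hypnogram file: {path}")
    if path.suffix.lower() in {".tsv", ".txt"}:
        return _read_hypnogram_tsv(path)
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = mne.read_annotations(path)
    entries = []
    for a in ann:
        text = a["description"].strip()
        if text not in ANNOTATION_TO_RAW:
            raise ValueError(f"unrecognised annotation {text!r} in {path.name}")
        entries.append((float(a["onset"]), float(a["duration"]), ANNOTATION_TO_RAW[text]))
    entries.sort(key=lambda e: e[0])
    return RawHypnogram(entries)


def _read_hypnogram_tsv(path: Path) -> RawHypnogram:
    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected 'epoch<TAB>stage'")
        idx, label = int(parts[0]), parts[1].strip()
        if label not in ANNOTATION_TO_RAW:
            raise ValueError(f"{path.name}:{lineno}: unknown stage {label!r}")
        entries.append(
            (idx * float(EPOCH_SECONDS), float(EPOCH_SECONDS), ANNOTATION_TO_RAW[label])
        )
    entries.sort(key=lambda e: e[0])
    return RawHypnogram(entries)


# ---------------------------------------------------------------------------
# harmonisation

def harmonise(
    recording: Recording,
    raw: RawHypnogram,
    wake_buffer: float = 30.0,
) -> tuple[Recording, Hypnogram]:
    """Align a recording with its hypnogram on the canonical alphabet.

    N3/N4 are merged into SWS; epochs scored "?" or MOVEMENT are dropped
    together with their signal; leading/trailing wake runs are truncated to at
    most ``wake_buffer`` minutes around the first/last non-wake epoch; the
    recording is cropped to the retained epochs.
    """
    spe = int(round(recording.rate * EPOCH_SECONDS))  # samples per epoch
    raw_labels = raw.epoch_labels()
    n_signal_epochs = len(recording.samples) // spe
    if len(raw_labels) != n_signal_epochs:
        warnings.warn(
            f"hypnogram ({len(raw_labels)} epochs) and recording "
            f"({n_signal_epochs} epochs) disagree; truncating to the shorter",
            stacklevel=2,
        )
    n = min(len(raw_labels), n_signal_epochs)
    raw_labels = raw_labels[:n]

    kept = [
        (i, RAW_TO_CANONICAL[lab])
        for i, lab in enumerate(raw_labels)
        if RAW_TO_CANONICAL[lab] is not None
    ]
    if not kept:
        raise ValueError("no scorable epochs after dropping '?' / MOVEMENT")
    labels = [lab for _, lab in kept]
    non_w = [j for j, lab in enumerate(labels) if lab != "W"]
    if not non_w:
        raise ValueError("all-wake hypnogram: no sleep to anchor wake trimming")

    buffer_epochs = int(round(wake_buffer * 60 / EPOCH_SECONDS))
    lo = max(0, non_w[0] - buffer_epochs)
    hi = min(len(labels), non_w[-1] + buffer_epochs + 1)
    retained = kept[lo:hi]

    pieces = [recording.samples[i * spe : (i + 1) * spe] for i, _ in retained]
    out = replace(recording, samples=np.concatenate(pieces))
    return out, Hypnogram([lab for _, lab in retained])


# ---------------------------------------------------------------------------
# writing (minimal EDF / EDF+ writer)

def _pad(value: object, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf_signal(path: Path, recording: Recording) -> None:
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # one data record per second
    x = recording.samples
    nrec = int(np.ceil(len(x) / spr))
    x = np.concatenate([x, np.zeros(nrec * spr - len(x))])
    pmin, pmax = float(x.min()), float(x.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    patient = f"{recording.id or 'X'} {recording.sex} {int(recording.age)}y"
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient, 80),
            _pad("Startdate 01-JAN-2000", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(256 * 2, 8),
            _pad("", 44),
            _pad(nrec, 8),
            _pad("1", 8),
            _pad("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _pad(recording.channel, 16),
            _pad("AgAgCl electrode", 80),
            _pad("uV", 8),
            _pad(f"{pmin:.8g}", 8),
            _pad(f"{pmax:.8g}", 8),
            _pad(dmin, 8),
            _pad(dmax, 8),
            _pad("", 80),
            _pad(spr, 8),
            _pad("", 32),
        ]
    )
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((x - pmin) / scale + dmin).astype("<i2")
    path.write_bytes(header + sig_header + digital.tobytes())


def _write_edf_annotations(path: Path, entries: list[tuple[float, float, str]]) -> None:
    records = []
    for onset, dur, text in entries:
        stamp = f"+{onset:g}\x14\x14\x00"
        tal = f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00"
        records.append((stamp + tal).encode("ascii"))
    recsize = max(len(r) for r in records)
    recsize += recsize % 2
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X", 80),
            _pad("Startdate 01-JAN-2000", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(256 * 2, 8),
            _pad("EDF+C", 44),
            _pad(len(records), 8),
            _pad("1", 8),
            _pad("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _pad("EDF Annotations", 16),
            _pad("", 80),
            _pad("", 8),
            _pad("-1", 8),
            _pad("1", 8),
            _pad("-32768", 8),
            _pad("32767", 8),
            _pad("", 80),
            _pad(recsize // 2, 8),
            _pad("", 32),
        ]
    )
    body = b"".join(r + b"\x00" * (recsize - len(r)) for r in records)
    path.write_bytes(header + sig_header + body)


def write_edf(
    recording: Recording,
    hypnogram: Hypnogram | RawHypnogram,
    path: str | Path,
) -> tuple[Path, Path]:
    """Write a paired ``<path>-PSG.edf`` / ``<path>-Hypnogram.edf``.

    Returns the two file paths. A JSON metadata sidecar is written next to
    the signal file. Both files read back with :func:`read_recording` /
    :func:`read_hypnogram`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    psg = path.parent / f"{path.name}-PSG.edf"
    hyp = path.parent / f"{path.name}-Hypnogram.edf"
    _write_edf_signal(psg, recording)
    psg.with_suffix(".meta.json").write_text(
        json.dumps({"id": recording.id, "age": recording.age, "sex": recording.sex})
    )
    if isinstance(hypnogram, Hypnogram):
        entries = [
            (i * hypnogram.epoch_length, hypnogram.epoch_length, lab)
            for i, lab in enumerate(hypnogram.stages)
        ]
        # canonical labels: SWS round-trips as N3 and maps back to SWS
        raw_labels = {"W": "W", "N1": "N1", "N2": "N2", "SWS": "N3", "REM": "REM"}
        entries = [(o, d, raw_labels[lab]) for o, d, lab in entries]
    else:
        entries = list(hypnogram.entries)
    ann = [(o, d, RAW_TO_ANNOTATION[lab]) for o, d, lab in entries]
    _write_edf_annotations(hyp, ann)
    return psg, hyp


def write_hypnogram_tsv(hypnogram: Hypnogram, path: str | Path) -> Path:
    """Write the plain TSV dialect: ``epoch_index<TAB>stage`` per line."""
    path = Path(path)
    path.write_text(
        "".join(f"{i}\t{lab}\n" for i, lab in enumerate(hypnogram.stages))
    )
    return path
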