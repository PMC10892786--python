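"""Band-pass filtering, 30-s epoching, normalisation, sub-band decomposition.

All filtering uses linear-phase hamming-window FIR designs applied with
exact group-delay compensation (odd tap count, ``fftconvolve`` in "same"
mode), i.e. effectively zero-phase: epoch-aligned waveforms such as spindle
bursts or K-complex pulses are not displaced in time.

The canonical analysis bands::

    δ 0.5–4, θ 4–8, α 9–11, σ 12–15, β1 14–20, β2 20–30,
    γ1 30–40, γ2 40–49.5, K-complex 0.5–1   (Hz)

α is narrowed to 9–11 Hz (adult posterior rhythm), β is split at 20 Hz to
separate wake (β1) from REM-dominant fast activity (β2), and γ is split at
40 Hz. The K-complex band deliberately overlaps δ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve, firwin

from .edf_io import Recording
from .stages import EPOCH_SECONDS

__all__ = [
    "Epoch",
    "BandDefinition",
    "DEFAULT_BANDS",
    "bandpass",
    "segment",
    "normalise",
    "subband_decompose",
    "load_band_table",
]


@dataclass
class Epoch:
    """One 30-s analysis window (3000 samples at 100 Hz)."""

    samples: np.ndarray
    rate: float
    index: int = 0
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.rate * EPOCH_SECONDS))
        if len(self.samples) != expected:
            raise ValueError(
                f"epoch must hold rate×{EPOCH_SECONDS} = {expected} samples, "
                f"got {len(self.samples)}"
            )


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float  # Hz
    high: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 9.0, 11.0),
    BandDefinition("sigma", 12.0, 15.0),
    BandDefinition("beta1", 14.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
    BandDefinition("gamma1", 30.0, 40.0),
    BandDefinition("gamma2", 40.0, 49.5),
    BandDefinition("kcomplex", 0.5, 1.0),
)


@lru_cache(maxsize=64)
def _design_fir(low: float, high: float, rate: float) -> np.ndarray:
    """Hamming-window band-pass FIR; transition width ≈ max(low, 0.5) Hz."""
    trans = max(low, 0.5)
    numtaps = int(np.ceil(3.3 * rate / trans))
    numtaps += 1 - numtaps % 2  # odd → integer group delay, exact compensation
    return firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=rate)


def _apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    if len(x) < len(taps):
        raise ValueError(
            f"signal ({len(x)} samples) shorter than filter order ({len(taps)})"
        )
    # odd-length linear-phase FIR: 'same' convolution = zero net phase;
    # odd-reflect padding suppresses edge transients (as filtfilt does)
    pad = len(taps) // 2
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2 : -pad - 2 : -1]
    padded = np.concatenate([left, x, right])
    return fftconvolve(padded, taps, mode="same")[pad:-pad]


def bandpass(recording: Recording, low: float = 0.5, high: float = 49.5) -> Recording:
    """Zero-phase hamming-window FIR band-pass; output length = input length."""
    if high >= recording.rate / 2:
        raise ValueError(
            f"upper edge {high} Hz must lie below Nyquist ({recording.rate / 2} Hz)"
        )
    taps = _design_fir(low, high, recording.rate)
    return replace(recording, samples=_apply_zero_phase(recording.samples, taps))


def segment(recording: Recording) -> list[Epoch]:
    """Split into consecutive non-overlapping 30-s epochs; remainder dropped."""
    spe_f = recording.rate * EPOCH_SECONDS
    if abs(spe_f - round(spe_f)) > 1e-9:
        raise ValueError("rate × 30 s must be an integer number of samples")
    spe = int(round(spe_f))
    n = len(recording.samples) // spe
    if n == 0:
        raise ValueError(
            f"recording ({len(recording.samples)} samples) shorter than one epoch"
        )
    return [
        Epoch(
            samples=recording.samples[i * spe : (i + 1) * spe],
            rate=recording.rate,
            index=i,
            recording_id=recording.id,
        )
        for i in range(n)
    ]


def normalise(epochs: list[Epoch]) -> list[Epoch]:
    """Per-recording z-score: pooled mean/sd over each recording's epochs.

    Normalising per recording (not per epoch) equalises amplitude across
    subjects while preserving the within-night amplitude contrast between
    stages, which carries staging information.
    """
    if not epochs:
        raise ValueError("no epochs to normalise")
    out: list[Epoch] = [None] * len(epochs)  # type: ignore[list-item]
    by_rec: dict[str, list[int]] = {}
    for i, ep in enumerate(epochs):
        by_rec.setdefault(ep.recording_id, []).append(i)
    for rec_id, idxs in by_rec.items():
        pooled = np.concatenate([epochs[i].samples for i in idxs])
        mu, sd = pooled.mean(), pooled.std()
        if sd == 0:
            raise ValueError(f"recording {rec_id!r} is constant: zero variance")
        for i in idxs:
            out[i] = replace(epochs[i], samples=(epochs[i].samples - mu) / sd)
    return out


def subband_decompose(
    epoch: Epoch, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, np.ndarray]:
    """Zero-phase band-filtered copy of the epoch per analysis band."""
    nyq = epoch.rate / 2
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if not 0 < band.low < band.high < nyq:
            raise ValueError(f"band {band.name}: edges outside (0, {nyq}) Hz")
        taps = _design_fir(band.low, band.high, epoch.rate)
        out[band.name] = _apply_zero_phase(epoch.samples, taps)
    return out


def load_band_table(path: str | Path) -> tuple[BandDefinition, ...]:
    """Load a band table: one ``name low_hz high_hz`` triple per line."""
    bands = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, low, high = line.split()
        bands.append(BandDefinition(name, float(low), float(high)))
    if not bands:
        raise ValueError(f"no bands defined in {path}")
    return tuple(bands)
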