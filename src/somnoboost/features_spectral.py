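"""Frequency-domain features: Welch PSD, per-band powers, total power.

The estimator is Welch's averaged periodogram with 4-s hamming segments and
50 % overlap (a conventional compromise for 30-s sleep epochs: 0.25 Hz
resolution, 14 averaged segments). Density scaling is used, so integrating
the density over frequency recovers signal variance up to windowing bias.
Band powers are trapezoidal integrals of the density over the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .preprocess import BandDefinition, Epoch

__all__ = ["SpectralEstimate", "welch_psd", "band_power", "total_psd_feature"]

SEGMENT_SECONDS = 4.0
OVERLAP_FRACTION = 0.5
TOTAL_BAND = (0.5, 49.5)  # Hz, for the scalar total-power feature


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray  # Hz, increasing from 0 to Nyquist
    density: np.ndarray  # power per Hz
    segment_seconds: float = SEGMENT_SECONDS
    overlap: float = OVERLAP_FRACTION
    window: str = "hamming"


def welch_psd(
    epoch: Epoch,
    segment_seconds: float = SEGMENT_SECONDS,
    overlap: float = OVERLAP_FRACTION,
    window: str = "hamming",
) -> SpectralEstimate:
    """Welch power spectral density of one epoch."""
    nperseg = int(round(segment_seconds * epoch.rate))
    if nperseg > len(epoch.samples):
        raise ValueError(
            f"segment ({nperseg} samples) longer than epoch ({len(epoch.samples)})"
        )
    freqs, density = welch(
        epoch.samples,
        fs=epoch.rate,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=False,
        scaling="density",
    )
    return SpectralEstimate(freqs, density, segment_seconds, overlap, window)


def band_power(spec: SpectralEstimate, band: BandDefinition) -> float:
    """Trapezoidal integral of the density over [band.low, band.high], µV²."""
    f, d = spec.frequencies, spec.density
    if band.low < f[0] or band.high > f[-1]:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) outside PSD grid "
            f"({f[0]}-{f[-1]} Hz)"
        )
    return _integrate(f, d, band.low, band.high)


def total_psd_feature(spec: SpectralEstimate) -> float:
    """Total integrated power over the analysis range (0.5–49.5 Hz)."""
    lo = max(TOTAL_BAND[0], spec.frequencies[0])
    hi = min(TOTAL_BAND[1], spec.frequencies[-1])
    return _integrate(spec.frequencies, spec.density, lo, hi)


def _integrate(f: np.ndarray, d: np.ndarray, lo: float, hi: float) -> float:
    # include exact band edges by interpolation so adjacent bands tile cleanly
    grid = np.union1d(f[(f >= lo) & (f <= hi)], [lo, hi])
    vals = np.interp(grid, f, d)
    return float(np.trapezoid(vals, grid))
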