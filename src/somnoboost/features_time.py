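"""Time-domain epoch features.

Moment conventions are population (1/M) throughout: variance, skewness
(third standardised moment) and kurtosis (fourth standardised moment,
non-excess — a Gaussian scores ≈ 3). The zero-crossing rate counts strict
sign changes (product of consecutive samples < 0) normalised by M−1; exact
zeros do not count as crossings. Hjorth derivatives are first differences in
sample units.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "basic_stats",
    "zero_crossing_rate",
    "hjorth",
    "band_energy",
    "band_ppa",
]


def basic_stats(signal: np.ndarray) -> dict[str, float]:
    """Mean, median, population variance/skewness/kurtosis, AMV, RMS.

    Zero-variance input yields skewness = kurtosis = 0 together with a
    ``degenerate`` flag in the returned dict.
    """
    x = np.asarray(signal, dtype=float)
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 samples")
    mean = float(x.mean())
    dev = x - mean
    var = float(np.mean(dev**2))
    degenerate = var == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(dev**3) / var**1.5)
        kurt = float(np.mean(dev**4) / var**2)
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "amv": float(np.max(np.abs(x))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "degenerate": degenerate,
    }


def zero_crossing_rate(signal: np.ndarray) -> float:
    """Fraction of consecutive-sample sign changes, in [0, 1]."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.count_nonzero(x[1:] * x[:-1] < 0) / (x.size - 1))


def hjorth(signal: np.ndarray) -> tuple[float, float]:
    """Hjorth (mobility, complexity).

    mobility = sqrt(var(Δx)/var(x)); complexity = mobility(Δx)/mobility(x).
    Mobility tracks the spectrum's mean frequency, complexity its spread.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_x = np.mean((x - x.mean()) ** 2)
    var_dx = np.mean((dx - dx.mean()) ** 2)
    var_ddx = np.mean((ddx - ddx.mean()) ** 2)
    if var_x == 0:
        raise ValueError("zero-variance signal: mobility undefined")
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx == 0:
        raise ValueError("constant first difference: complexity undefined")
    complexity = float(np.sqrt(var_ddx / var_dx) / mobility)
    return mobility, complexity


def band_energy(band_signal: np.ndarray) -> float:
    """Σ|x|² over the (sub-band filtered) epoch, in µV²·samples."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.sum(np.abs(x) ** 2))


def band_ppa(band_signal: np.ndarray) -> float:
    """Peak-to-peak amplitude: max − min."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(x.max() - x.min())
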