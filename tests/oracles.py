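"""Independent brute-force oracles used to cross-check feature implementations.

Everything here is written as directly as possible from the defining
formulas — explicit Python loops, no shared code with the package — so that
agreement between package and oracle is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def stats_oracle(x):
    x = list(map(float, x))
    m = len(x)
    mean = sum(x) / m
    var = sum((v - mean) ** 2 for v in x) / m
    out = {
        "mean": mean,
        "median": float(np.median(x)),
        "variance": var,
        "amv": max(abs(v) for v in x),
        "rms": math.sqrt(sum(v * v for v in x) / m),
    }
    if var > 0:
        out["skewness"] = (sum((v - mean) ** 3 for v in x) / m) / var**1.5
        out["kurtosis"] = (sum((v - mean) ** 4 for v in x) / m) / var**2
    else:
        out["skewness"] = out["kurtosis"] = 0.0
    return out


def zcr_oracle(x):
    crossings = sum(1 for a, b in zip(x[:-1], x[1:]) if a * b < 0)
    return crossings / (len(x) - 1)


def hjorth_oracle(x):
    def popvar(v):
        mu = sum(v) / len(v)
        return sum((u - mu) ** 2 for u in v) / len(v)

    dx = [b - a for a, b in zip(x[:-1], x[1:])]
    ddx = [b - a for a, b in zip(dx[:-1], dx[1:])]
    mob = math.sqrt(popvar(dx) / popvar(x))
    mob_dx = math.sqrt(popvar(ddx) / popvar(dx))
    return mob, mob_dx / mob


def energy_oracle(x):
    return sum(abs(v) ** 2 for v in x)


def ppa_oracle(x):
    return max(x) - min(x)


def shannon_oracle(x, bins=10):
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if lo == hi:
        return 0.0
    counts = [0] * bins
    for v in x:
        idx = min(int((v - lo) / (hi - lo) * bins), bins - 1)
        counts[idx] += 1
    n = len(x)
    return -sum(c / n * math.log(c / n) for c in counts if c)


def perm_entropy_oracle(x, order=3, delay=1):
    patterns = {}
    span = (order - 1) * delay
    for i in range(len(x) - span):
        window = [x[i + j * delay] for j in range(order)]
        # stable argsort: rank by (value, temporal position)
        pattern = tuple(sorted(range(order), key=lambda j: (window[j], j)))
        patterns[pattern] = patterns.get(pattern, 0) + 1
    n = sum(patterns.values())
    return -sum(c / n * math.log(c / n) for c in patterns.values())


def svd_entropy_oracle(x, dim=10, delay=1):
    rows = []
    span = (dim - 1) * delay
    for i in range(len(x) - span):
        rows.append([x[i + j * delay] for j in range(dim)])
    sv = np.linalg.svd(np.array(rows), compute_uv=False)
    p = sv / sv.sum()
    return float(-sum(v * math.log(v) for v in p if v > 0))


def sampen_oracle(x, m=2, r_factor=0.2):
    x = list(map(float, x))
    n = len(x)
    sd = math.sqrt(sum((v - sum(x) / n) ** 2 for v in x) / n)
    r = r_factor * sd
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def lz76_oracle(bits):
    """Exhaustive-history parse: next word = shortest prefix of the remainder
    not occurring as a substring of everything before its last symbol."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    words = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        words += 1
        i += k
    return words


def mmd_oracle(x, window=100):
    total = 0.0
    for start in range(0, len(x) - window + 1, window):
        w = list(x[start : start + window])
        vmax, vmin = max(w), min(w)
        dx = abs(w.index(vmax) - w.index(vmin))
        total += math.sqrt(dx**2 + (vmax - vmin) ** 2)
    return total


def pfd_oracle(x):
    diff = [b - a for a, b in zip(x[:-1], x[1:])]
    k = sum(1 for a, b in zip(diff[:-1], diff[1:]) if a * b < 0)
    m = len(x)
    return math.log(m) / (math.log(m) + math.log(m / (m + 0.4 * k)))


def kfd_oracle(x):
    m = len(x)
    path = sum(math.hypot(1.0, b - a) for a, b in zip(x[:-1], x[1:]))
    d = max(math.hypot(i, v - x[0]) for i, v in enumerate(x))
    if d == 0 or path == 0:
        return 1.0
    ln = math.log(m - 1)
    return ln / (ln + math.log(d / path))


def higuchi_oracle(x, kmax=10):
    """Plain-loop Higuchi curve-length slope."""
    n = len(x)
    log_lk, log_inv_k = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            lengths.append(dist * (n - 1) / ((len(idx) - 1) * k) / k)
        mean_l = sum(lengths) / len(lengths)
        if mean_l > 0:
            log_lk.append(math.log(mean_l))
            log_inv_k.append(math.log(1.0 / k))
    slope = np.polyfit(log_inv_k, log_lk, 1)[0]
    return float(slope)


def periodogram_psd_oracle(x, fs, nperseg, noverlap):
    """Hamming-windowed averaged periodogram, density scaling (manual Welch)."""
    x = np.asarray(x, float)
    # periodic hamming, the spectral-analysis convention
    win = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    step = nperseg - noverlap
    norm = fs * np.sum(win**2)
    spectra = []
    start = 0
    while start + nperseg <= len(x):
        seg = x[start : start + nperseg] * win
        spec = np.abs(np.fft.rfft(seg)) ** 2 / norm
        spec[1:-1] *= 2  # one-sided
        spectra.append(spec)
        start += step
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    return freqs, np.mean(spectra, axis=0)


def trapz_band_oracle(freqs, density, lo, hi):
    grid = sorted(set([lo, hi] + [f for f in freqs if lo <= f <= hi]))
    vals = np.interp(grid, freqs, density)
    total = 0.0
    for i in range(1, len(grid)):
        total += 0.5 * (vals[i] + vals[i - 1]) * (grid[i] - grid[i - 1])
    return total


def kappa_oracle(y_true, y_pred):
    n = len(y_true)
    po = sum(1 for a, b in zip(y_true, y_pred) if a == b) / n
    classes = set(y_true) | set(y_pred)
    pe = sum(
        (sum(1 for v in y_true if v == c) * sum(1 for v in y_pred if v == c))
        for c in classes
    ) / n**2
    return (po - pe) / (1 - pe)
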