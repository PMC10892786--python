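"""Entropy, complexity, fractal-dimension and long-range-dependence features.

All logarithms are natural, so entropies are in nats. Parameters that the
sleep-staging literature leaves open are set to conventional defaults
(histogram entropy: 10 equal-width bins; permutation entropy: order 3,
delay 1; sample entropy: m = 2, r = 0.2·sd; SVD entropy: 10×1 embedding;
MMD window: 100 samples = 1 s at 100 Hz; Higuchi k_max = 10) and are all
overridable per call.

The O(n²) template counting of sample entropy and the Lempel–Ziv parse are
numba-compiled so full 3000-sample epochs remain cheap; the test suite
checks both against plain brute-force oracles.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

from .features_spectral import welch_psd
from .preprocess import Epoch

__all__ = [
    "shannon_entropy",
    "permutation_entropy",
    "spectral_entropy",
    "svd_entropy",
    "sample_entropy",
    "lempel_ziv",
    "max_min_distance",
    "fractal_dims",
    "long_range",
]


def _discrete_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shannon_entropy(signal: np.ndarray, bins: int = 10) -> float:
    """Histogram (amplitude-distribution) entropy, equal-width bins in nats."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.min() == x.max():  # single occupied bin
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    return _discrete_entropy(counts / x.size)


def permutation_entropy(signal: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Entropy of the ordinal-pattern distribution (ties by temporal order)."""
    x = np.asarray(signal, dtype=float)
    span = (order - 1) * delay + 1
    if x.size < span + 1:
        raise ValueError(f"need at least {span + 1} samples for order {order}")
    windows = sliding_window_view(x, span)[:, ::delay]
    ranks = np.argsort(windows, axis=1, kind="stable")
    base = order ** np.arange(order)
    codes = ranks @ base
    _, counts = np.unique(codes, return_counts=True)
    return _discrete_entropy(counts / codes.size)


def spectral_entropy(epoch: Epoch) -> float:
    """Entropy of the Welch PSD normalised to a distribution over bins."""
    spec = welch_psd(epoch)
    total = spec.density.sum()
    if total <= 0:
        raise ValueError("zero total power: spectral entropy undefined")
    return _discrete_entropy(spec.density / total)


def svd_entropy(signal: np.ndarray, embed_dim: int = 10, embed_delay: int = 1) -> float:
    """Entropy of normalised singular values of the delay-embedding matrix."""
    x = np.asarray(signal, dtype=float)
    span = (embed_dim - 1) * embed_delay + 1
    if x.size < span:
        raise ValueError(f"need at least {span} samples for embedding {embed_dim}")
    traj = sliding_window_view(x, span)[:, ::embed_delay]
    sv = np.linalg.svd(traj, compute_uv=False)
    total = sv.sum()
    if total == 0:
        raise ValueError("all-zero trajectory matrix")
    return _discrete_entropy(sv / total)


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b += 1
                diff = abs(x[i + m] - x[j + m])
                if diff <= r:  # Chebyshev over m+1 points given d <= r
                    a += 1
    return a, b


def sample_entropy(signal: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy −ln(A/B) with Chebyshev tolerance r = r_factor·sd.

    A counts matching (m+1)-templates, B matching m-templates, self-matches
    excluded. If either count is zero the value is undefined; the
    Richman–Moorman upper bound −ln(2/((n−m−1)(n−m))) is returned with a
    warning so downstream feature matrices stay finite.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} samples")
    r = r_factor * float(x.std())
    if r <= 0:
        raise ValueError("constant signal: tolerance r = 0")
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        cap = -np.log(2.0 / ((n - m - 1) * (n - m)))
        warnings.warn("sample entropy undefined (no template matches); capped")
        return float(cap)
    return float(-np.log(a / b))


@njit(cache=True)
def _lz76_count(s: np.ndarray) -> int:
    """Number of words in the LZ76 exhaustive-history parse of a binary array."""
    n = s.shape[0]
    i = 0  # candidate match start within history
    c = 1
    length = 1  # parsed prefix length
    k = 1
    kmax = 1
    while True:
        if s[i + k - 1] == s[length + k - 1]:
            k += 1
            if length + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == length:
                c += 1
                length += kmax
                if length + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


def lempel_ziv(signal: np.ndarray) -> int:
    """LZ76 complexity of the signal binarised at its median (x ≥ med → 1)."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size == 1:
        return 1
    binary = (x >= np.median(x)).astype(np.uint8)
    return int(_lz76_count(binary))


def max_min_distance(signal: np.ndarray, window: int = 100) -> float:
    """Sum over non-overlapping windows of √(Δx² + Δy²).

    Δx is the index distance between the window's maximum and minimum
    (first occurrence on ties), Δy their amplitude difference. A trailing
    partial window is dropped.
    """
    x = np.asarray(signal, dtype=float)
    if window > x.size:
        raise ValueError(f"window ({window}) longer than signal ({x.size})")
    n_win = x.size // window
    blocks = x[: n_win * window].reshape(n_win, window)
    imax = blocks.argmax(axis=1)
    imin = blocks.argmin(axis=1)
    dx = np.abs(imax - imin)
    dy = blocks.max(axis=1) - blocks.min(axis=1)
    return float(np.sum(np.sqrt(dx**2 + dy**2)))


def _higuchi(x: np.ndarray, kmax: int) -> float:
    n = x.size
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (((idx.size - 1)) * k)
            lm.append(dist * norm / k)
        lk[k - 1] = np.mean(lm)
    ks = np.arange(1, kmax + 1)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(1.0 / ks[valid]), np.log(lk[valid]), 1)[0]
    return float(slope)


def fractal_dims(
    signal: np.ndarray, hfd_kmax: int = 10
) -> tuple[float, float, float]:
    """(Petrosian, Katz, Higuchi) fractal dimensions.

    Petrosian binarises via sign changes of the first difference
    (K = their count): PFD = log M / (log M + log(M / (M + 0.4K))).
    Katz: KFD = log n / (log n + log(d/L)) with n = number of steps, L the
    total path length in the index–value plane, d the maximum distance from
    the first point. Higuchi is the slope of the log–log curve-length decay.
    """
    x = np.asarray(signal, dtype=float)
    m = x.size
    if m < 4:
        raise ValueError("need at least 4 samples")

    diff = np.diff(x)
    k_changes = int(np.count_nonzero(diff[1:] * diff[:-1] < 0))
    log_m = np.log(m)
    pfd = float(log_m / (log_m + np.log(m / (m + 0.4 * k_changes))))

    steps = np.hypot(np.ones(m - 1), diff)  # unit index spacing
    path = float(steps.sum())
    d = float(np.max(np.hypot(np.arange(m), x - x[0])))
    if d == 0 or path == 0:
        kfd = 1.0  # constant signal: degenerate, dimension of a point/line
    else:
        log_n = np.log(m - 1)
        kfd = float(log_n / (log_n + np.log(d / path)))

    hfd = _higuchi(x, hfd_kmax)
    return pfd, kfd, hfd


def long_range(signal: np.ndarray) -> tuple[float, float]:
    """(DFA exponent, Hurst exponent).

    DFA: linear-detrended fluctuation of the integrated series over
    log-spaced window sizes 4 … n/4, slope of log F(s) vs log s.
    Hurst: rescaled-range (R/S) log–log slope over log-spaced chunk sizes.
    White noise scores ≈ 0.5 on both; its running sum scores DFA ≈ 1.5.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples")
    if x.std() == 0:
        raise ValueError("zero-variance signal")

    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.logspace(np.log10(4), np.log10(n // 4), 12).astype(int))
    flucts = np.empty(sizes.size)
    t_template = {}
    for si, s in enumerate(sizes):
        n_win = n // s
        segs = profile[: n_win * s].reshape(n_win, s)
        t = t_template.setdefault(s, np.arange(s, dtype=float))
        coeffs = np.polyfit(t, segs.T, 1)
        trend = np.outer(coeffs[0], t) + coeffs[1][:, None]
        flucts[si] = np.sqrt(np.mean((segs - trend) ** 2))
    dfa_alpha = float(np.polyfit(np.log(sizes), np.log(flucts), 1)[0])

    rs_sizes = np.unique(
        np.logspace(np.log10(10), np.log10(n // 2), 10).astype(int)
    )
    rs_vals = []
    for s in rs_sizes:
        n_win = n // s
        segs = x[: n_win * s].reshape(n_win, s)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)
        ok = sd > 0
        if ok.any():
            rs_vals.append(np.mean(r[ok] / sd[ok]))
        else:
            rs_vals.append(np.nan)
    rs_vals = np.asarray(rs_vals)
    ok = np.isfinite(rs_vals) & (rs_vals > 0)
    hurst = float(np.polyfit(np.log(rs_sizes[ok]), np.log(rs_vals[ok]), 1)[0])
    return dfa_alpha, hurst
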