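"""Feature-matrix assembly, temporal feature shifting, folds and balancing.

Each 30-s epoch yields a fixed 52-column feature vector: the subject's age,
24 whole-epoch statistics/complexity measures, and — per analysis band —
the filtered sub-band signal's energy, its spectral power and its
peak-to-peak amplitude (9 bands × 3 = 27 columns).

Feature shifting then appends, per non-age column, the previous epoch's and
next epoch's value (``.lag1`` / ``.lead1``), giving 3 × 51 + 1 = 154
columns. Shifting never crosses a recording boundary: terminal epochs
replicate their own row, so no subject's context leaks into another's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features_complexity as fc
from . import features_spectral as fs
from . import features_time as ft
from .edf_io import Hypnogram, Recording
from .preprocess import DEFAULT_BANDS, BandDefinition, Epoch, bandpass, normalise, segment, subband_decompose
from .stages import STAGE_TO_INT

__all__ = [
    "BASE_COLUMNS",
    "META_COLUMNS",
    "assemble",
    "extract_features",
    "shift_features",
    "stratified_folds",
    "balance_training",
    "feature_columns",
]

META_COLUMNS = ("recording_id", "epoch", "stage")

_EPOCH_COLUMNS = (
    "mean",
    "median",
    "abs_max",
    "variance",
    "skewness",
    "kurtosis",
    "rms",
    "ppa",
    "entropy",
    "perm_entropy",
    "spectral_entropy",
    "svd_entropy",
    "sample_entropy",
    "katz_fd",
    "higuchi_fd",
    "zero_crossings",
    "dfa",
    "hurst",
    "mmd",
    "lzc",
    "hjorth_mobility",
    "hjorth_complexity",
    "psd",
    "petrosian_fd",
)


def _band_columns(bands: tuple[BandDefinition, ...]) -> list[str]:
    names = [b.name for b in bands]
    return (
        [f"energy_{n}" for n in names]
        + [f"power_{n}" for n in names]
        + [f"amp_{n}" for n in names]
    )


#: The canonical 52-column feature schema (age + 24 epoch + 27 band columns).
BASE_COLUMNS: tuple[str, ...] = tuple(
    ["age", *_EPOCH_COLUMNS, *_band_columns(DEFAULT_BANDS)]
)


def assemble(
    epoch: Epoch,
    subbands: dict[str, np.ndarray],
    spectral: fs.SpectralEstimate,
    age: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, float]:
    """Compute the 52-feature row for one epoch.

    Raises on any non-finite feature, naming the feature and epoch.
    """
    x = epoch.samples
    stats = ft.basic_stats(x)
    if stats.pop("degenerate"):
        raise ValueError(
            f"epoch {epoch.index} of {epoch.recording_id!r} has zero variance"
        )
    mobility, complexity = ft.hjorth(x)
    pfd, kfd, hfd = fc.fractal_dims(x)
    dfa_alpha, hurst = fc.long_range(x)

    row: dict[str, float] = {
        "age": float(age),
        "mean": stats["mean"],
        "median": stats["median"],
        "abs_max": stats["amv"],
        "variance": stats["variance"],
        "skewness": stats["skewness"],
        "kurtosis": stats["kurtosis"],
        "rms": stats["rms"],
        "ppa": ft.band_ppa(x),
        "entropy": fc.shannon_entropy(x),
        "perm_entropy": fc.permutation_entropy(x),
        "spectral_entropy": fc.spectral_entropy(epoch),
        "svd_entropy": fc.svd_entropy(x),
        "sample_entropy": fc.sample_entropy(x),
        "katz_fd": kfd,
        "higuchi_fd": hfd,
        "zero_crossings": ft.zero_crossing_rate(x),
        "dfa": dfa_alpha,
        "hurst": hurst,
        "mmd": fc.max_min_distance(x),
        "lzc": float(fc.lempel_ziv(x)),
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "psd": fs.total_psd_feature(spectral),
        "petrosian_fd": pfd,
    }
    for band in bands:
        row[f"energy_{band.name}"] = ft.band_energy(subbands[band.name])
    for band in bands:
        row[f"power_{band.name}"] = fs.band_power(spectral, band)
    for band in bands:
        row[f"amp_{band.name}"] = ft.band_ppa(subbands[band.name])

    for name, value in row.items():
        if not np.isfinite(value):
            raise ValueError(
                f"feature {name!r} is {value} on epoch {epoch.index} "
                f"of {epoch.recording_id!r}"
            )
    return row


def extract_features(
    recording: Recording,
    hypnogram: Hypnogram,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    low: float = 0.5,
    high: float = 49.5,
) -> pd.DataFrame:
    """Full per-recording pipeline: band-pass → segment → normalise → features.

    Returns one row per epoch with the 52 feature columns plus
    ``recording_id``, ``epoch`` and integer ``stage``.
    """
    filtered = bandpass(recording, low, high)
    epochs = normalise(segment(filtered))
    if len(epochs) != len(hypnogram):
        raise ValueError(
            f"{recording.id!r}: {len(epochs)} epochs vs "
            f"{len(hypnogram)} hypnogram labels"
        )
    rows = []
    for ep, stage in zip(epochs, hypnogram.stages):
        subbands = subband_decompose(ep, bands)
        spectral = fs.welch_psd(ep)
        row = assemble(ep, subbands, spectral, recording.age, bands)
        row["recording_id"] = recording.id
        row["epoch"] = ep.index
        row["stage"] = STAGE_TO_INT[stage]
        rows.append(row)
    return pd.DataFrame(rows, columns=[*BASE_COLUMNS, *META_COLUMNS])


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a feature matrix, in order."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


def shift_features(matrix: pd.DataFrame, m: int = 1) -> pd.DataFrame:
    """Append ±m-epoch lag/lead copies of every non-age feature column.

    For the default m = 1 a 52-feature matrix becomes 154 columns
    (3 × 51 + age). Rows must be grouped by recording in temporal order;
    boundary rows replicate the recording's own terminal row so context
    never crosses recordings.
    """
    cols = [c for c in feature_columns(matrix) if c != "age"]
    if "recording_id" in matrix.columns:
        rec = matrix["recording_id"]
        order_ok = all(
            group["epoch"].is_monotonic_increasing
            for _, group in matrix.groupby("recording_id", sort=False)
        ) if "epoch" in matrix.columns else True
        if not order_ok:
            raise ValueError("rows must be in temporal order within recordings")
        grouped = matrix.groupby(rec, sort=False)
    else:
        grouped = None

    out = matrix.copy()
    new_cols: dict[str, pd.Series] = {}
    for j in range(1, m + 1):
        for col in cols:
            if grouped is not None:
                lag = grouped[col].shift(j)
                lead = grouped[col].shift(-j)
            else:
                lag = matrix[col].shift(j)
                lead = matrix[col].shift(-j)
            new_cols[f"{col}.lag{j}"] = lag.fillna(matrix[col])
            new_cols[f"{col}.lead{j}"] = lead.fillna(matrix[col])
    out = pd.concat([out, pd.DataFrame(new_cols, index=matrix.index)], axis=1)
    # keep metadata last
    feats = [c for c in out.columns if c not in META_COLUMNS]
    meta = [c for c in META_COLUMNS if c in out.columns]
    return out[[*feats, *meta]]


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified k-fold assignment (fold id per row, 0..k−1)."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    rare = classes[counts < k]
    if rare.size:
        raise ValueError(f"classes {rare.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    plan = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        plan[test_idx] = fold
    return plan


def balance_training(
    rows: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random oversampling with replacement up to the majority-class count.

    Applies to training folds only (the caller's responsibility, enforced by
    the evaluation pipeline). Every emitted row is a copy of an input row.
    """
    rows = np.asarray(rows)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any():
        raise ValueError("empty class")
    target = counts.max()
    keep = [np.arange(labels.size)]
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            idx = np.flatnonzero(labels == cls)
            keep.append(rng.choice(idx, size=target - cnt, replace=True))
    sel = np.concatenate(keep)
    return rows[sel], labels[sel]
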