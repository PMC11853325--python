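"""Per-window statistical features and the 99-column feature table.

Twelve features per channel per window — Min, Max, mean, population
standard deviation, RMS, skewness, non-excess kurtosis, crest factor,
shape factor, mean absolute deviation, median absolute deviation and
L2 norm — over 8 channels give 96 feature columns; Participant,
EMG_Time (window start) and Risk complete the 99-column table.

Conventions: all moments use the population (1/n) normalization; the
crest numerator is max|x| so negative-dominated windows stay
well-defined; the shape denominator is the mean of absolute values
(the mean itself is ~0 for zero-mean EMG and would explode the ratio);
kurtosis is non-excess (Gaussian -> 3).  Degenerate windows (sigma = 0
or RMS = 0) yield zeros for the affected ratio features rather than
NaN, so models never see missing values; their count is recorded in
``DataFrame.attrs["degenerate_windows"]``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocessing import WindowBatch

FEATURE_NAMES = ("Min", "Max", "Mean", "Std", "RMS", "Skewness", "Kurtosis",
                 "Crest", "Shape", "MeanAD", "MedianAD", "L2")
METADATA_COLUMNS = ("Participant", "EMG_Time", "Risk")


def feature_columns(n_channels: int = 8,
                    channel_names=None) -> list[str]:
    """The 96 feature-column names, Sensor 1 block first."""
    if channel_names is None:
        channel_names = [f"Sensor {i}" for i in range(1, n_channels + 1)]
    return [f"{ch}_{feat}" for ch in channel_names for feat in FEATURE_NAMES]


def _features_2d(w: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized 12 features for windows stacked as (n_windows, n_samples).

    Returns (n_windows, 12) plus the number of degenerate windows.
    """
    n = w.shape[1]
    mn = w.min(axis=1)
    mx = w.max(axis=1)
    mu = w.mean(axis=1)
    centered = w - mu[:, None]
    var = np.mean(centered**2, axis=1)
    sd = np.sqrt(var)
    ms = np.mean(w**2, axis=1)
    rms = np.sqrt(ms)
    absw = np.abs(w)
    mean_abs = absw.mean(axis=1)
    max_abs = absw.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, np.mean(centered**3, axis=1) / sd**3, 0.0)
        kurt = np.where(sd > 0, np.mean(centered**4, axis=1) / sd**4, 0.0)
        crest = np.where(rms > 0, max_abs / rms, 0.0)
        shape = np.where(rms > 0, rms / mean_abs, 0.0)
    mean_ad = np.abs(centered).mean(axis=1)
    med = np.median(w, axis=1)
    median_ad = np.median(np.abs(w - med[:, None]), axis=1)
    l2 = np.sqrt(w.shape[1] * ms)
    degenerate = int(np.sum((sd == 0) | (rms == 0)))
    out = np.stack([mn, mx, mu, sd, rms, skew, kurt, crest, shape,
                    mean_ad, median_ad, l2], axis=1)
    return out, degenerate


def window_features(x) -> dict[str, float]:
    """The 12 features of a single window (1-D signal of n >= 2 samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("window_features expects a 1-D signal")
    if len(x) < 2:
        raise ValueError("need at least 2 samples per window")
    values, degenerate = _features_2d(x[None, :])
    if degenerate:
        warnings.warn("degenerate window (zero variance or zero RMS); "
                      "ratio features set to 0", stacklevel=2)
    return dict(zip(FEATURE_NAMES, values[0]))


def featurize_batch(batch: WindowBatch, chunk_size: int = 4096) -> pd.DataFrame:
    """One row per window, 99 columns (96 features + metadata).

    Windows are processed in chunks so strided views over long
    recordings never materialize at once.
    """
    if len(batch) == 0:
        raise ValueError("cannot featurize an empty batch")
    if batch.window_size < 2:
        raise ValueError("need at least 2 samples per window")
    n_w = len(batch)
    n_ch = batch.windows.shape[2]
    values = np.empty((n_w, n_ch * len(FEATURE_NAMES)))
    degenerate = 0
    for start in range(0, n_w, chunk_size):
        block = np.asarray(batch.windows[start : start + chunk_size])
        for c in range(n_ch):
            feats, bad = _features_2d(block[:, :, c])
            cols = slice(c * len(FEATURE_NAMES), (c + 1) * len(FEATURE_NAMES))
            values[start : start + len(block), cols] = feats
            degenerate += bad
    df = pd.DataFrame(values, columns=feature_columns(n_ch, batch.channel_names))
    df["Participant"] = batch.participant_id
    df["EMG_Time"] = batch.start_time
    df["Risk"] = batch.risk_label
    if degenerate:
        warnings.warn(f"{degenerate} degenerate channel-windows; ratio features "
                      "set to 0", stacklevel=2)
    df.attrs["degenerate_windows"] = degenerate
    return df
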