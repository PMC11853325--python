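"""Recording CSV I/O, z-score normalization and sliding-window segmentation.

The on-disk dialect is the 11-column layout used throughout the
analysis: ``Participant, EMG_Time, Sensor 1 ... Sensor 8, Risk`` with
one row per sample, Risk literally '0' (low-risk 10 lb lift) or '1'
(high-risk 18 lb lift).  An optional leading line stating the sampling
frequency is tolerated on read and skipped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import CHANNEL_NAMES, N_CHANNELS, EmgRecording

EXPECTED_COLUMNS = ("Participant", "EMG_Time", *CHANNEL_NAMES, "Risk")

_RATE_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)")


class EmgCsvError(ValueError):
    """Malformed recording CSV."""


class ColumnCountError(EmgCsvError):
    pass


class TimestampError(EmgCsvError):
    pass


class RiskLabelError(EmgCsvError):
    pass


def write_emg_csv(recording: EmgRecording, path,
                  rate_header: bool = False) -> None:
    """Write the 11-column CSV; floats use shortest-repr (lossless) form.

    ``rate_header=True`` prepends the sampling-frequency line some
    acquisition exports carry.
    """
    df = pd.DataFrame({"Participant": recording.participant_id,
                       "EMG_Time": recording.timestamps})
    for i, name in enumerate(recording.channel_names):
        df[name] = recording.data[:, i]
    df["Risk"] = recording.risk_label
    with open(path, "w", newline="") as fh:
        if rate_header:
            fh.write(f"Sampling frequency: {recording.sampling_rate} Hz\n")
        df.to_csv(fh, index=False)


def read_emg_csv(path) -> EmgRecording:
    """Read a recording; inverse of :func:`write_emg_csv`.

    A first line that is not the 11-column header (e.g. a sampling
    frequency note) is skipped; the rate is then parsed from it, and
    otherwise inferred from the median timestamp spacing.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
    skip = 0
    rate: Optional[float] = None
    if "Participant" not in first or "EMG_Time" not in first:
        skip = 1
        match = _RATE_RE.search(first)
        if match:
            rate = float(match.group(1))
    # round_trip parsing keeps write->read lossless (< 1e-9 s on timestamps)
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if tuple(df.columns) != EXPECTED_COLUMNS:
        raise ColumnCountError(
            f"expected 11 columns {list(EXPECTED_COLUMNS)}, got {list(df.columns)}")
    t = df["EMG_Time"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise TimestampError("EMG_Time must be strictly increasing")
    risk_values = set(df["Risk"].unique().tolist())
    if not risk_values <= {0, 1}:
        raise RiskLabelError(f"Risk column must be binary 0/1, got {sorted(risk_values)}")
    if len(risk_values) != 1:
        raise RiskLabelError("Risk column must be constant within one recording")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return EmgRecording(
        participant_id=str(df["Participant"].iloc[0]),
        sampling_rate=rate,
        timestamps=t,
        data=df[list(CHANNEL_NAMES)].to_numpy(dtype=float),
        risk_label=int(df["Risk"].iloc[0]),
    )


def znormalize(x, strict: bool = True) -> np.ndarray:
    """(x - mean) / population-sd along the first axis.

    A zero-variance channel raises in strict mode and maps to zeros in
    lenient mode.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise EmgCsvError("znormalize needs at least 2 samples")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (1/n) convention
    zero = sd == 0
    if np.any(zero):
        if strict:
            raise ZeroDivisionError("zero-variance signal; use strict=False for zeros")
        sd = np.where(zero, 1.0, sd)
        return np.where(zero, 0.0, (x - mu) / sd)
    return (x - mu) / sd


def normalize_recording(recording: EmgRecording, scope: str = "recording",
                        strict: bool = False) -> EmgRecording:
    """Per-channel z-normalization over the whole recording.

    ``scope="recording"`` (default) preserves within-recording amplitude
    structure; ``scope="none"`` returns the input unchanged.  Per-window
    scope is applied at segmentation time (see :func:`sliding_windows`).
    """
    if scope == "none":
        return recording
    if scope != "recording":
        raise EmgCsvError(f"unknown normalization scope {scope!r}")
    return EmgRecording(
        participant_id=recording.participant_id,
        sampling_rate=recording.sampling_rate,
        timestamps=recording.timestamps,
        data=znormalize(recording.data, strict=strict),
        risk_label=recording.risk_label,
        channel_names=recording.channel_names,
    )


@dataclass
class WindowBatch:
    """Overlapping fixed-length segments with per-window metadata.

    ``windows`` has shape (n_windows, window_size, n_channels); it may be
    a strided view into the recording, so windows from a single
    recording cost no extra memory.
    """

    windows: np.ndarray
    participant_id: np.ndarray   # (n_windows,) str
    risk_label: np.ndarray       # (n_windows,) int
    start_time: np.ndarray       # (n_windows,) s
    window_size: int
    stride: int
    channel_names: tuple = CHANNEL_NAMES

    def __len__(self) -> int:
        return len(self.windows)

    @classmethod
    def empty(cls, window_size: int, stride: int) -> "WindowBatch":
        return cls(windows=np.empty((0, window_size, N_CHANNELS)),
                   participant_id=np.empty(0, dtype=object),
                   risk_label=np.empty(0, dtype=int),
                   start_time=np.empty(0), window_size=window_size, stride=stride)

    @classmethod
    def concatenate(cls, batches: list["WindowBatch"]) -> "WindowBatch":
        if not batches:
            raise EmgCsvError("cannot concatenate zero batches")
        sizes = {b.window_size for b in batches}
        strides = {b.stride for b in batches}
        if len(sizes) != 1 or len(strides) != 1:
            raise EmgCsvError("batches disagree on window_size/stride")
        return cls(
            windows=np.concatenate([b.windows for b in batches]),
            participant_id=np.concatenate([b.participant_id for b in batches]),
            risk_label=np.concatenate([b.risk_label for b in batches]),
            start_time=np.concatenate([b.start_time for b in batches]),
            window_size=sizes.pop(), stride=strides.pop(),
            channel_names=batches[0].channel_names,
        )


def window_count(n_samples: int, window_size: int, stride: int) -> int:
    """floor((N - size)/stride) + 1, or 0 when the recording is too short."""
    if n_samples < window_size:
        return 0
    return (n_samples - window_size) // stride + 1


def sliding_windows(recording: EmgRecording, window_size: int = 400,
                    stride: int = 1, normalize_windows: bool = False,
                    on_short: str = "warn") -> WindowBatch:
    """Segment one recording into overlapping windows.

    Windows are indexed by start sample (0-based, half-open
    ``[start, start + window_size)``) and never cross recording
    boundaries — segment each recording separately and concatenate the
    batches.  ``normalize_windows=True`` z-scores each window per
    channel (the degenerate per-window scope; off by default).
    A recording shorter than one window yields an empty batch with a
    warning, or raises with ``on_short="error"``.
    """
    if window_size < 2:
        raise EmgCsvError("window_size must be >= 2")
    if stride < 1:
        raise EmgCsvError("stride must be >= 1")
    n = recording.n_samples
    count = window_count(n, window_size, stride)
    if count == 0:
        if on_short == "error":
            raise EmgCsvError(f"recording of {n} samples shorter than window "
                              f"({window_size})")
        warnings.warn(f"recording of {n} samples yields no {window_size}-sample "
                      "windows", stacklevel=2)
        return WindowBatch.empty(window_size, stride)
    view = np.lib.stride_tricks.sliding_window_view(
        recording.data, window_size, axis=0)[::stride]
    windows = view.transpose(0, 2, 1)  # (n_w, window_size, channels), still a view
    if normalize_windows:
        mu = windows.mean(axis=1, keepdims=True)
        sd = windows.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        windows = (windows - mu) / sd
    starts = np.arange(count) * stride
    return WindowBatch(
        windows=windows,
        participant_id=np.full(count, recording.participant_id, dtype=object),
        risk_label=np.full(count, recording.risk_label, dtype=int),
        start_time=recording.timestamps[starts],
        window_size=window_size, stride=stride,
        channel_names=recording.channel_names,
    )
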