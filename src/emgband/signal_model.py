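"""Core signal containers and file I/O.

A :class:`SignalTrace` holds a uniformly sampled multi-channel voltage series
in millivolts.  Traces are read from and written to two plain interchange
formats: CSV (``time_s`` column followed by one column per channel) and
IEEE-float WAV (sampling rate taken from the header, samples stored in mV
without normalization so physical units survive a round trip).

Windowing follows causal semantics throughout the package: a frame's
timestamp is the time of its *last* sample, i.e. the instant at which the
frame's feature value first becomes available to a streaming consumer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import EmptyInputError, MalformedInputError

#: Relative tolerance on timestamp uniformity when inferring fs from a CSV
#: time column.
TIME_JITTER_RTOL = 1e-6


@dataclass
class SignalTrace:
    """Uniformly sampled multi-channel voltage series.

    Parameters
    ----------
    samples:
        Array of shape ``(n_samples, n_channels)`` in millivolts.
    fs:
        Sampling rate in Hz, strictly positive.
    channel_names:
        One label per channel (e.g. ``["flexor", "extensor"]``).
    t0:
        Start time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise MalformedInputError("samples must be a 2-D (n_samples, n_channels) array")
        if self.samples.shape[0] == 0:
            raise EmptyInputError("a SignalTrace must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise MalformedInputError("samples must be finite")
        if not self.fs > 0:
            raise MalformedInputError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.samples.shape[1]))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[1]:
            raise MalformedInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.samples[:, idx]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis-window geometry.

    ``length_samples`` is the FFT size N when used for spectral analysis and
    must then be a power of two; ``hop_samples`` is the stride between
    consecutive frames.
    """

    length_samples: int
    hop_samples: int
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.length_samples < 1 or self.hop_samples < 1:
            raise MalformedInputError("window length and hop must be positive")
        if self.hop_samples > self.length_samples:
            raise MalformedInputError("hop must not exceed window length")

    def n_frames(self, n_samples: int) -> int:
        """Number of full frames a signal of ``n_samples`` yields."""
        if n_samples < self.length_samples:
            return 0
        return (n_samples - self.length_samples) // self.hop_samples + 1


def frames(trace: SignalTrace, spec: WindowSpec) -> Iterator[tuple[int, np.ndarray]]:
    """Yield causal sliding windows ``(start_index, window_samples)``.

    Windows advance by ``spec.hop_samples``; a trailing partial window is
    discarded.  ``window_samples`` has shape ``(length_samples, n_channels)``.
    A trace shorter than one window yields an empty sequence.
    """
    L, h = spec.length_samples, spec.hop_samples
    for k in range(spec.n_frames(trace.n_samples)):
        start = k * h
        yield start, trace.samples[start : start + L]


def read_trace(path: str | os.PathLike, format: str | None = None) -> SignalTrace:
    """Read a :class:`SignalTrace` from CSV or WAV.

    CSV must carry a leading time column (seconds) plus one column per
    channel (mV); fs is inferred as 1/median(dt) and timestamps must be
    uniform to within :data:`TIME_JITTER_RTOL` relative tolerance.  WAV takes
    fs from the header and samples as stored.
    """
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "wav":
        return _read_wav(path)
    raise MalformedInputError(f"unsupported format {fmt!r} (expected 'csv' or 'wav')")


def write_trace(trace: SignalTrace, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a trace to CSV (``time_s`` + one mV column per channel) or float32 WAV."""
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.DataFrame({"time_s": trace.times})
        for i, name in enumerate(trace.channel_names):
            df[name] = trace.samples[:, i]
        df.to_csv(path, index=False)
    elif fmt == "wav":
        data = trace.samples.astype(np.float32)
        if data.shape[1] == 1:
            data = data[:, 0]
        wavfile.write(path, int(round(trace.fs)), data)
    else:
        raise MalformedInputError(f"unsupported format {fmt!r} (expected 'csv' or 'wav')")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    return ext if ext else "csv"


def _read_csv(path: str) -> SignalTrace:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no data rows")
    if df.shape[1] < 2:
        raise MalformedInputError(f"{path} needs a time column plus >=1 channel column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise MalformedInputError(f"{path}: at least two rows needed to infer fs")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise MalformedInputError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - med)) > TIME_JITTER_RTOL * med:
        raise MalformedInputError(
            f"{path}: non-uniform timestamps (jitter beyond {TIME_JITTER_RTOL:g} "
            "relative tolerance)"
        )
    samples = df.iloc[:, 1:].to_numpy(dtype=float)
    names = tuple(str(c) for c in df.columns[1:])
    return SignalTrace(samples=samples, fs=1.0 / med, channel_names=names, t0=float(t[0]))


def _read_wav(path: str) -> SignalTrace:
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.size == 0:
        raise EmptyInputError(f"{path} contains no samples")
    if data.ndim == 1:
        data = data[:, None]
    if np.issubdtype(data.dtype, np.integer):
        # integer PCM: scale to [-1, 1) full scale
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return SignalTrace(samples=data.astype(float), fs=float(fs))
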