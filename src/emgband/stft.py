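"""Streaming short-time Fourier transform replicating the embedded pipeline.

The embedded controller samples at 1,100 Hz and applies a 256-point FFT to a
sliding window, giving a bin spacing of 1100/256 ≈ 4.3 Hz.  Frames are
causal: a frame's timestamp is the time of its last sample, the earliest
instant at which its spectrum can exist on a streaming device.

Magnitudes are one-sided and amplitude-normalized by ``2/sum(g)`` (``1/sum(g)``
at DC and Nyquist), so a unit-amplitude on-bin sinusoid reads ≈ 1 mV
regardless of taper.  Thresholds calibrated on these magnitudes are therefore
in input-voltage units, which is what "voltage amplitude of the frequency
band" means here.

The default taper is Hann.  A rectangular taper (as a bare MCU FFT would use)
is available, but Hann's lower sidelobes are what keep 50/60 Hz mains leakage
out of the 60–80 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .errors import MalformedInputError
from .features import FeatureSeries, band_magnitude
from .signal_model import SignalTrace, WindowSpec, frames

DEFAULT_FS = 1100.0
DEFAULT_FFT_LEN = 256
DEFAULT_HOP = 64


@dataclass(frozen=True)
class STFTConfig:
    """Analysis geometry of the streaming STFT."""

    fft_len: int = DEFAULT_FFT_LEN
    hop: int = DEFAULT_HOP
    fs: float = DEFAULT_FS
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.fft_len < 2 or (self.fft_len & (self.fft_len - 1)) != 0:
            raise MalformedInputError("fft_len must be a power of two >= 2")
        if not (0 < self.hop <= self.fft_len):
            raise MalformedInputError("hop must be in (0, fft_len]")
        if self.fs <= 0:
            raise MalformedInputError("fs must be positive")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.fft_len, self.hop, self.taper)

    @property
    def bin_hz(self) -> float:
        """Frequency resolution fs / fft_len (≈ 4.297 Hz at defaults)."""
        return self.fs / self.fft_len

    def taper_values(self) -> np.ndarray:
        if self.taper == "rectangular":
            return np.ones(self.fft_len)
        return get_window(self.taper, self.fft_len, fftbins=True)


@dataclass
class SpectralFrame:
    """One-sided magnitude spectrum of a single analysis window."""

    t_s: float
    freqs_hz: np.ndarray
    magnitude: np.ndarray  # shape (fft_len//2 + 1,) or (nbins, n_channels)

    def band_magnitude(self, lo_hz: float = 60.0, hi_hz: float = 80.0) -> float | np.ndarray:
        return band_magnitude(self.freqs_hz, self.magnitude, lo_hz, hi_hz)


@dataclass
class Spectrogram:
    """Time-ordered spectral frames for a (possibly multi-channel) trace."""

    frames: list[SpectralFrame] = field(default_factory=list)
    channel_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t_s for f in self.frames])


def _frame_magnitude(window: np.ndarray, g: np.ndarray) -> np.ndarray:
    """One-sided amplitude-normalized magnitude of one tapered window."""
    X = np.fft.rfft(g[:, None] * window, axis=0)
    mag = np.abs(X) * (2.0 / g.sum())
    mag[0] /= 2.0
    if window.shape[0] % 2 == 0:
        mag[-1] /= 2.0
    return mag


def stft(trace: SignalTrace, config: STFTConfig | None = None) -> Spectrogram:
    """Batch STFT of a trace; empty spectrogram if shorter than one frame."""
    config = config or STFTConfig(fs=trace.fs)
    if abs(config.fs - trace.fs) > 1e-9 * trace.fs:
        raise MalformedInputError(
            f"config fs {config.fs} does not match trace fs {trace.fs}"
        )
    g = config.taper_values()
    freqs = np.fft.rfftfreq(config.fft_len, d=1.0 / config.fs)
    out = Spectrogram(channel_names=trace.channel_names)
    for start, window in frames(trace, config.window_spec):
        t_s = trace.t0 + (start + config.fft_len - 1) / config.fs
        out.frames.append(SpectralFrame(t_s=t_s, freqs_hz=freqs, magnitude=_frame_magnitude(window, g)))
    return out


class StreamingSTFT:
    """Incremental STFT emitting each frame as soon as its last sample arrives.

    Feeding any chunking of a signal through :meth:`push` produces exactly the
    frames batch :func:`stft` would, in the same order.
    """

    def __init__(self, config: STFTConfig | None = None, n_channels: int = 1, t0: float = 0.0):
        self.config = config or STFTConfig()
        self.n_channels = n_channels
        self.t0 = t0
        self._g = self.config.taper_values()
        self._freqs = np.fft.rfftfreq(self.config.fft_len, d=1.0 / self.config.fs)
        self._buffer = np.empty((0, n_channels))
        self._consumed = 0  # samples dropped from the front of the buffer

    def push(self, chunk: np.ndarray) -> list[SpectralFrame]:
        """Append samples; return all frames completed by this chunk."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        if chunk.shape[1] != self.n_channels and chunk.shape[0] == self.n_channels:
            chunk = chunk.T
        if chunk.shape[1] != self.n_channels:
            raise MalformedInputError(
                f"chunk has {chunk.shape[1]} channels, expected {self.n_channels}"
            )
        self._buffer = np.vstack([self._buffer, chunk])
        L, h, fs = self.config.fft_len, self.config.hop, self.config.fs
        out: list[SpectralFrame] = []
        while self._buffer.shape[0] >= L:
            window = self._buffer[:L]
            start = self._consumed
            t_s = self.t0 + (start + L - 1) / fs
            out.append(
                SpectralFrame(t_s=t_s, freqs_hz=self._freqs, magnitude=_frame_magnitude(window, self._g))
            )
            self._buffer = self._buffer[h:]
            self._consumed += h
        return out


def stream_stft(chunks, config: STFTConfig | None = None, n_channels: int = 1, t0: float = 0.0):
    """Generator form of :class:`StreamingSTFT` over an iterable of chunks."""
    engine = StreamingSTFT(config, n_channels=n_channels, t0=t0)
    for chunk in chunks:
        yield from engine.push(chunk)


def band_series(
    spectrogram: Spectrogram,
    lo_hz: float = 60.0,
    hi_hz: float = 80.0,
    channel: int | str = 0,
) -> FeatureSeries:
    """Per-frame mean in-band magnitude as a time series for one channel."""
    if isinstance(channel, str):
        idx = spectrogram.channel_names.index(channel)
        name = channel
    else:
        idx = channel
        name = (
            spectrogram.channel_names[idx]
            if idx < len(spectrogram.channel_names)
            else f"ch{idx}"
        )
    times, values = [], []
    for frame in spectrogram.frames:
        mag = frame.magnitude[:, idx] if frame.magnitude.ndim == 2 else frame.magnitude
        times.append(frame.t_s)
        values.append(band_magnitude(frame.freqs_hz, mag, lo_hz, hi_hz))
    return FeatureSeries(
        times_s=np.array(times),
        values=np.array(values),
        feature_name="BANDMAG",
        channel=name,
        units="mV",
    )
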