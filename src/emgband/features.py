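"""Time-domain and frequency-domain EMG features.

Four scalar features are used throughout the package:

* ``riemg`` — rectified-and-integrated EMG, the rectangular-rule
  discretization of the windowed integral of |x(t)| (mV·s),
* ``rms`` — root mean square over a window (mV),
* ``fmed`` / ``fmean`` — median and mean frequency of a power spectrum (Hz),
* ``band_magnitude`` — the mean one-sided spectral magnitude over a fixed
  frequency band, here 60–80 Hz, the quantity the frequency-domain trigger
  monitors (mV).

Conventions that matter for reproducibility:

* ``fmean`` weights frequencies by the *linear* spectral values.  A dB
  weighting (available via ``db=True``) makes the statistic depend on an
  arbitrary reference level and breaks invariance to signal scaling, so it is
  not the default.
* ``fmed`` treats each bin's power as spread uniformly over its bin-width
  interval and interpolates linearly inside the half-power crossing bin, which
  removes bin-width quantization (a single occupied bin yields exactly its
  center frequency).
* ``band_magnitude`` averages (not sums) the magnitudes of bins whose center
  frequency lies in the closed band, so its scale does not depend on the FFT
  length and one calibrated threshold works across window configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .errors import DegenerateSpectrumError, EmptyBandError, EmptyInputError

FEATURE_NAMES = ("RIEMG", "RMS", "FMED", "FMEAN", "BANDMAG")


@dataclass
class FeatureSeries:
    """Time-indexed scalar feature values for one channel."""

    times_s: np.ndarray
    values: np.ndarray
    feature_name: str
    channel: str = ""
    units: str = "mV"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PowerSpectrum:
    """One-sided spectrum: PSD (mV²/Hz) or linear magnitude (mV), per ``kind``."""

    freqs_hz: np.ndarray
    power: np.ndarray
    kind: str = "psd"  # "psd" | "magnitude"

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if len(self.freqs_hz) and self.freqs_hz[0] < 0:
            raise ValueError("frequencies must be non-negative")
        if len(self.freqs_hz) > 1 and not np.all(np.diff(self.freqs_hz) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("spectral values must be non-negative")


def riemg(window: np.ndarray, fs: float) -> float:
    """Rectified-and-integrated EMG over one window, in mV·s.

    Rectangular-rule discretization of the integral of |x(t)| over the
    window: ``sum(|x_i|) / fs``.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise EmptyInputError("riemg of an empty window")
    return float(np.sum(np.abs(window)) / fs)


def rms(window: np.ndarray) -> float:
    """Root mean square of one window: sqrt(mean(x_i^2)), in mV."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise EmptyInputError("rms of an empty window")
    return float(np.sqrt(np.mean(np.square(window))))


def psd(window: np.ndarray, fs: float, taper: str = "hann") -> PowerSpectrum:
    """Tapered one-sided periodogram of one window.

    The returned density is the PSD of the *tapered* signal: with bin width
    ``Δf = fs/L``, ``sum(power)·Δf`` equals the mean square of ``g·x``
    (Parseval).  Bin centers are ``k·fs/L``.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise EmptyInputError("psd needs a window of length >= 2")
    L = x.size
    g = get_window(taper, L, fftbins=True) if taper != "rectangular" else np.ones(L)
    X = np.fft.rfft(g * x)
    scale = np.full(X.size, 2.0)
    scale[0] = 1.0
    if L % 2 == 0:
        scale[-1] = 1.0
    Pxx = scale * np.abs(X) ** 2 / (L * fs)
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    return PowerSpectrum(freqs_hz=freqs, power=Pxx, kind="psd")


def fmed(spectrum: PowerSpectrum) -> float:
    """Median frequency: where the cumulative power reaches half the total.

    Each bin's power is taken as uniformly distributed over its bin-width
    interval centered on the bin frequency; the half-power point is found by
    linear interpolation inside the crossing bin.
    """
    P = spectrum.power
    total = float(P.sum())
    if total <= 0:
        raise DegenerateSpectrumError("median frequency of a zero-power spectrum")
    f = spectrum.freqs_hz
    if len(f) == 1:
        return float(f[0])
    df = float(np.median(np.diff(f)))
    edges = np.concatenate([[f[0] - df / 2.0], f + df / 2.0])
    cum = np.concatenate([[0.0], np.cumsum(P)])
    return float(np.interp(total / 2.0, cum, edges))


def fmean(spectrum: PowerSpectrum, db: bool = False, db_floor: float = 1e-12) -> float:
    """Mean frequency: intensity-weighted mean of bin frequencies.

    ``sum(I_i·f_i) / sum(I_i)`` with the linear spectral values as weights.
    With ``db=True`` the weights are ``10·log10(P/max(P))`` shifted to be
    non-negative — retained only for comparison, since a dB weighting depends
    on the reference level.
    """
    I = spectrum.power
    if db:
        ref = float(I.max())
        if ref <= 0:
            raise DegenerateSpectrumError("mean frequency of a zero-power spectrum")
        I = 10.0 * np.log10(np.maximum(I, db_floor * ref) / (db_floor * ref))
    total = float(I.sum())
    if total <= 0:
        raise DegenerateSpectrumError("mean frequency of a zero-power spectrum")
    return float(np.sum(I * spectrum.freqs_hz) / total)


def band_magnitude(
    freqs_hz: np.ndarray, magnitude: np.ndarray, lo_hz: float = 60.0, hi_hz: float = 80.0
) -> float:
    """Mean spectral magnitude over bins with center frequency in [lo, hi].

    At the embedded configuration (fs 1,100 Hz, 256-point FFT) the 60–80 Hz
    band comprises bins 14–18 (60.16–77.34 Hz).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    mask = (freqs_hz >= lo_hz) & (freqs_hz <= hi_hz)
    if not mask.any():
        raise EmptyBandError(f"no spectral bins with center frequency in [{lo_hz}, {hi_hz}] Hz")
    return float(np.mean(magnitude[mask]))
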