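"""Synthetic two-channel surface-EMG episodes.

The generator emulates the statistical structure of forearm sEMG as seen by a
two-sensor (flexor / extensor) acquisition chain:

* **Contraction carrier** — a zero-mean Gaussian process shaped so that its
  power concentrates in 30–200 Hz with the most prominent content in
  60–80 Hz peaking near 70 Hz.  It is the sum of a broadband component
  (white noise through a 3rd-order Butterworth band-pass, 35–110 Hz) and a
  resonant component (white noise through a second-order peaking filter at
  ``spectral_peak_hz``, Q = 5) carrying 35% of the power.  No motor-unit
  physiology is claimed; the process simply matches the target spectrum.
* **Activation envelope** — raised-cosine on/off ramps of 100 ms, so onset
  latency of a downstream detector is well defined.
* **Antagonist behaviour** — during a FLEX interval the flexor channel
  carries the contraction process while the extensor stays at rest level
  (plus a small cross-talk fraction), and vice versa.
* **Artifacts** — additive powerline sinusoid (50 Hz default, i.e. outside
  the monitored 60–80 Hz band), a < 20 Hz motion artifact (low-passed noise),
  and optional broadband noise.  The separation of these artifacts from the
  60–80 Hz band is the testable core of the fixed-band approach.

Everything is reproducible from one integer seed; per-channel and
per-component sub-streams are derived deterministically via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .errors import InvalidLabelsError, MalformedInputError
from .signal_model import SignalTrace

STATES = ("FLEX", "EXT", "REST")

# Carrier shaping constants (see module docstring).
RESONANT_POWER_FRACTION = 0.35
BROADBAND_BAND_HZ = (35.0, 110.0)
BROADBAND_ORDER = 3
RESONANCE_Q = 5.0
ENVELOPE_RISE_S = 0.1
#: Default inter-subject relative SDs (coefficients of variation) of
#: contraction RMS and 60–80 Hz band magnitude.
DEFAULT_RMS_SPREAD = 0.46
DEFAULT_BAND_SPREAD = 0.43
DEFAULT_FS = 1100.0

_LEAD_IN_S = 1.0  # extra synthesis time discarded to flush filter transients


@dataclass
class SubjectProfile:
    """Per-subject amplitude and spectral parameters.

    ``gain_per_channel`` multiplies the broadband component of the contraction
    process; ``band_gain`` multiplies the resonant (60–80 Hz) component.  For
    a default subject both are 1, so contraction RMS is ``contraction_mv``.
    Decoupling the two gains is what lets a cohort show large variability in
    whole-signal RMS but small variability in the fixed-band magnitude.
    """

    gain_per_channel: tuple[float, float] = (1.0, 1.0)
    band_gain: float = 1.0
    spectral_peak_hz: float = 70.0
    rest_noise_mv: float = 40.0
    contraction_mv: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain_per_channel) or self.band_gain <= 0:
            raise MalformedInputError("gains must be positive")
        if not 30.0 <= self.spectral_peak_hz <= 200.0:
            raise MalformedInputError("spectral_peak_hz must be in [30, 200]")
        if not self.rest_noise_mv < self.contraction_mv:
            raise MalformedInputError("rest_noise_mv must be below contraction_mv")


@dataclass
class EpisodeLabels:
    """Ground-truth state intervals ``(start_s, end_s, state)`` of an episode."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise InvalidLabelsError("labels must contain at least one interval")
        prev_end = None
        for start, end, state in self.intervals:
            if state not in STATES:
                raise InvalidLabelsError(f"unknown state {state!r}")
            if not end > start:
                raise InvalidLabelsError(f"interval ({start}, {end}) has non-positive length")
            if prev_end is not None and start < prev_end - 1e-12:
                raise InvalidLabelsError("intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]

    def active_intervals(self, state: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, st in self.intervals if st == state]

    @classmethod
    def from_sequence(cls, states_durations: list[tuple[str, float]]) -> "EpisodeLabels":
        """Build contiguous labels from ``[(state, duration_s), ...]``."""
        t, out = 0.0, []
        for state, dur in states_durations:
            out.append((t, t + dur, state))
            t += dur
        return cls(out)


@dataclass
class ArtifactSpec:
    """Additive contaminations applied to both channels."""

    powerline_hz: float = 50.0
    powerline_amp_mv: float = 0.0
    motion_artifact_cutoff_hz: float = 20.0
    motion_artifact_amp_mv: float = 0.0
    broadband_noise_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.powerline_hz not in (50.0, 60.0):
            raise MalformedInputError("powerline_hz must be 50 or 60")
        for amp in (self.powerline_amp_mv, self.motion_artifact_amp_mv, self.broadband_noise_mv):
            if amp < 0:
                raise MalformedInputError("artifact amplitudes must be >= 0")

    @classmethod
    def standard(cls, contraction_mv: float = 400.0) -> "ArtifactSpec":
        """Powerline at 0.3× and motion artifact at 0.5× the nominal contraction RMS."""
        return cls(powerline_amp_mv=0.3 * contraction_mv, motion_artifact_amp_mv=0.5 * contraction_mv)


# ---------------------------------------------------------------------------
# carrier construction


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, kind: str, peak_hz: float) -> np.ndarray:
    """Unit-RMS shaped Gaussian noise (broadband or resonant component)."""
    lead = int(_LEAD_IN_S * fs)
    white = rng.standard_normal(n + lead)
    if kind == "broadband":
        sos = sps.butter(BROADBAND_ORDER, BROADBAND_BAND_HZ, "bandpass", fs=fs, output="sos")
        y = sps.sosfilt(sos, white)
    else:
        b, a = sps.iirpeak(peak_hz, RESONANCE_Q, fs=fs)
        y = sps.lfilter(b, a, white)
    y = y[lead:]
    std = y.std()
    return y / std if std > 0 else y


def _mixed_carrier(rng: np.random.Generator, n: int, fs: float, peak_hz: float,
                   g_bb: float, g_band: float) -> np.ndarray:
    """Contraction process with component gains; unit RMS when both gains are 1."""
    pr = RESONANT_POWER_FRACTION
    bb = _shaped_noise(rng, n, fs, "broadband", peak_hz)
    res = _shaped_noise(rng, n, fs, "resonant", peak_hz)
    return g_bb * np.sqrt(1.0 - pr) * bb + g_band * np.sqrt(pr) * res


def _envelope(n: int, fs: float, intervals: list[tuple[float, float]],
              rise_s: float = ENVELOPE_RISE_S) -> np.ndarray:
    """Raised-cosine activation envelope: 0 at rest, 1 during contraction."""
    env = np.zeros(n)
    t = np.arange(n) / fs
    for start, end in intervals:
        r = min(rise_s, (end - start) / 2.0)
        seg = (t >= start) & (t < end)
        ts = t[seg]
        e = np.ones(ts.size)
        rising = ts < start + r
        e[rising] = 0.5 * (1.0 - np.cos(np.pi * (ts[rising] - start) / r))
        falling = ts >= end - r
        e[falling] = 0.5 * (1.0 - np.cos(np.pi * (end - ts[falling]) / r))
        env[seg] = np.maximum(env[seg], e)
    return env


def synth_episode(
    profile: SubjectProfile,
    labels: EpisodeLabels,
    artifacts: ArtifactSpec | None = None,
    fs: float = DEFAULT_FS,
    duration_s: float | None = None,
    cross_talk: float = 0.1,
) -> SignalTrace:
    """Generate one labeled two-channel episode.

    Channel 0 ("flexor") carries the contraction process during FLEX
    intervals, channel 1 ("extensor") during EXT intervals; the antagonist
    stays at rest level plus ``cross_talk`` times the agonist's contraction
    signal.  A continuous rest-level carrier (same spectral shape, amplitude
    ``rest_noise_mv``) underlies both channels, and artifacts are added last.
    """
    if fs < 500.0:
        raise MalformedInputError("fs must be >= 500 Hz to represent 0-250 Hz content")
    artifacts = artifacts or ArtifactSpec()
    duration = duration_s if duration_s is not None else labels.duration
    if labels.duration > duration + 1e-9:
        raise InvalidLabelsError(
            f"labels extend to {labels.duration} s beyond requested {duration} s"
        )
    n = int(round(duration * fs))
    if n < 1:
        raise InvalidLabelsError("episode duration must cover at least one sample")

    streams = np.random.SeedSequence(profile.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    peak = profile.spectral_peak_hz

    chans = []
    active = {"flexor": labels.active_intervals("FLEX"), "extensor": labels.active_intervals("EXT")}
    contraction = {}
    for c, name in enumerate(("flexor", "extensor")):
        rest = _shaped_noise(rngs[c], n, fs, "broadband", peak) * np.sqrt(1 - RESONANT_POWER_FRACTION)
        rest = rest + _shaped_noise(rngs[c + 2], n, fs, "resonant", peak) * np.sqrt(RESONANT_POWER_FRACTION)
        rest *= profile.rest_noise_mv
        carrier = _mixed_carrier(rngs[c + 4], n, fs, peak,
                                 profile.gain_per_channel[c], profile.band_gain)
        contraction[name] = profile.contraction_mv * carrier * _envelope(n, fs, active[name])
        chans.append(rest + contraction[name])
    chans[0] = chans[0] + cross_talk * contraction["extensor"]
    chans[1] = chans[1] + cross_talk * contraction["flexor"]

    out = np.column_stack(chans)

    # Artifact amplitudes are RMS values, so contributions compose predictably.
    if artifacts.powerline_amp_mv > 0:
        phase = rngs[6].uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        out += (artifacts.powerline_amp_mv * np.sqrt(2.0)
                * np.sin(2 * np.pi * artifacts.powerline_hz * t + phase))[:, None]

    lead = int(_LEAD_IN_S * fs)
    noise_rngs = [np.random.default_rng(s) for s in streams[7].spawn(2)]
    if artifacts.motion_artifact_amp_mv > 0:
        sos = sps.butter(4, artifacts.motion_artifact_cutoff_hz, "lowpass", fs=fs, output="sos")
        for c in range(2):
            motion = sps.sosfilt(sos, noise_rngs[c].standard_normal(n + lead))[lead:]
            std = motion.std()
            if std > 0:
                out[:, c] += motion / std * artifacts.motion_artifact_amp_mv
    if artifacts.broadband_noise_mv > 0:
        for c in range(2):
            out[:, c] += artifacts.broadband_noise_mv * noise_rngs[c].standard_normal(n)

    return SignalTrace(samples=out, fs=fs, channel_names=("flexor", "extensor"))


def rectify_integrate(trace: SignalTrace, tau_s: float) -> SignalTrace:
    """Full-wave rectification followed by a first-order low-pass.

    Emulates the envelope output of an integrating EMG sensor: per channel
    ``y[k] = a·y[k-1] + (1-a)·|x[k]|`` with ``a = exp(-1/(fs·tau_s))``.  DC
    gain is 1, the output is non-negative, and an impulse decays with ratio
    ``a`` between successive samples.
    """
    if tau_s <= 0:
        raise MalformedInputError("tau_s must be positive")
    a = np.exp(-1.0 / (trace.fs * tau_s))
    rect = np.abs(trace.samples)
    env = sps.lfilter([1.0 - a], [1.0, -a], rect, axis=0)
    return SignalTrace(samples=env, fs=trace.fs,
                       channel_names=trace.channel_names, t0=trace.t0)


# ---------------------------------------------------------------------------
# cohort construction


@lru_cache(maxsize=32)
def _component_band_fractions(fs: float, peak_hz: float,
                              lo_hz: float = 60.0, hi_hz: float = 80.0) -> tuple[float, float]:
    """Fractions of each carrier component's power inside [lo, hi] Hz.

    Computed from the actual filter frequency responses, so the cohort gain
    solver below stays consistent with whatever shaping constants are in use.
    """
    w = np.linspace(0.0, fs / 2.0, 8192)
    sos = sps.butter(BROADBAND_ORDER, BROADBAND_BAND_HZ, "bandpass", fs=fs, output="sos")
    _, h_bb = sps.sosfreqz(sos, worN=w, fs=fs)
    b, a = sps.iirpeak(peak_hz, RESONANCE_Q, fs=fs)
    _, h_res = sps.freqz(b, a, worN=w, fs=fs)
    band = (w >= lo_hz) & (w <= hi_hz)
    p_bb, p_res = np.abs(h_bb) ** 2, np.abs(h_res) ** 2
    return float(p_bb[band].sum() / p_bb.sum()), float(p_res[band].sum() / p_res.sum())


def _solve_component_gains(
    s_rms_sq: float, s_band_sq: float, fs: float, peak_hz: float
) -> tuple[float, float]:
    """Broadband and resonant gains realizing target RMS/band power scales.

    Solves ``pb·g_bb² + pr·g_band² = s_rms²`` and the analogous normalized
    in-band equation for the band scale; non-physical negative solutions are
    clipped to a small positive floor.
    """
    qb, qr = _component_band_fractions(fs, peak_hz)
    pr = RESONANT_POWER_FRACTION
    pb = 1.0 - pr
    d0 = qb * pb + qr * pr
    A = np.array([[pb, pr], [qb * pb / d0, qr * pr / d0]])
    sol = np.linalg.solve(A, np.array([s_rms_sq, s_band_sq]))
    g_bb, g_band = np.sqrt(np.maximum(sol, 1e-4))
    return float(g_bb), float(g_band)


#: Within-subject session-to-session drift (CV of the session scale factor).
#: Whole-signal RMS drifts appreciably between recording sessions while the
#: 60–80 Hz band magnitude stays stable — the reason the time-domain
#: controller needs onsite recalibration.
DEFAULT_RMS_SESSION_DRIFT = 0.15
DEFAULT_BAND_SESSION_DRIFT = 0.05


def session_variation(
    profile: SubjectProfile,
    session_seed: int,
    rms_drift: float = DEFAULT_RMS_SESSION_DRIFT,
    band_drift: float = DEFAULT_BAND_SESSION_DRIFT,
    fs: float = DEFAULT_FS,
) -> SubjectProfile:
    """Return the profile as it presents in a new recording session.

    Draws log-normal session factors (mean 1, CVs ``rms_drift`` /
    ``band_drift``) for the subject's contraction RMS and band-magnitude
    scales and re-solves the component gains.  The episode seed is replaced
    by ``session_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(session_seed), profile.seed]))

    def factor(cv: float) -> float:
        if cv == 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return float(np.exp(sigma * rng.standard_normal() - sigma**2 / 2.0))

    qb, qr = _component_band_fractions(fs, profile.spectral_peak_hz)
    pr = RESONANT_POWER_FRACTION
    pb = 1.0 - pr
    d0 = qb * pb + qr * pr
    g_bb_sq = profile.gain_per_channel[0] ** 2
    g_band_sq = profile.band_gain**2
    s_rms_sq = pb * g_bb_sq + pr * g_band_sq
    s_band_sq = (qb * pb * g_bb_sq + qr * pr * g_band_sq) / d0
    g_bb, g_band = _solve_component_gains(
        s_rms_sq * factor(rms_drift) ** 2,
        s_band_sq * factor(band_drift) ** 2,
        fs,
        profile.spectral_peak_hz,
    )
    return SubjectProfile(
        gain_per_channel=(g_bb, g_bb),
        band_gain=g_band,
        spectral_peak_hz=profile.spectral_peak_hz,
        rest_noise_mv=profile.rest_noise_mv,
        contraction_mv=profile.contraction_mv,
        seed=int(session_seed) % (2**31),
    )


def make_cohort(
    n_subjects: int,
    rms_spread: float = DEFAULT_RMS_SPREAD,
    band_spread: float = DEFAULT_BAND_SPREAD,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    spectral_peak_hz: float = 70.0,
    correlation: float = 0.8,
    **profile_kwargs,
) -> list[SubjectProfile]:
    """Draw a cohort whose contraction RMS and 60–80 Hz band magnitude have
    the requested inter-subject coefficients of variation.

    Each subject gets a target scale for contraction RMS and one for band
    magnitude, drawn from correlated log-normals with mean 1 and the given
    CVs; the broadband and resonant component gains realising those scales
    are obtained from the components' total- and in-band power fractions
    (2×2 linear system; non-physical negative solutions are clipped).
    """
    if n_subjects < 1:
        raise MalformedInputError("n_subjects must be >= 1")
    if rms_spread < 0 or band_spread < 0:
        raise MalformedInputError("spreads must be >= 0")
    seq = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(n_subjects + 1)]
    if n_subjects == 1:
        return [SubjectProfile(seed=subject_seeds[0],
                               spectral_peak_hz=spectral_peak_hz, **profile_kwargs)]

    rng = np.random.default_rng(seq.spawn(1)[0])
    # Correlated log-normal subject scales, drawn with per-coordinate
    # stratification (Latin-hypercube style): a correlated bivariate normal
    # fixes the rank coupling between the two scales, then each coordinate's
    # values are replaced by stratified quantiles in the same rank order.
    # Each marginal is then sampled almost exactly, so the realized cohort CV
    # tracks the requested spread even for small cohorts.
    from scipy.stats import norm

    z_shared = rng.standard_normal(n_subjects)
    raw = {
        "rms": np.sqrt(correlation) * z_shared
        + np.sqrt(1 - correlation) * rng.standard_normal(n_subjects),
        "band": np.sqrt(correlation) * z_shared
        + np.sqrt(1 - correlation) * rng.standard_normal(n_subjects),
    }

    quantiles = norm.ppf((np.arange(n_subjects) + 0.5) / n_subjects)

    def scales(cv: float, z: np.ndarray) -> np.ndarray:
        """Log-normal scale factors with sample CV equal to ``cv``.

        The cohort's values are the midpoint-stratified quantiles of a
        log-normal, assigned in the rank order of ``z``; sigma is solved so
        the discretized sample CV hits the requested spread exactly.
        """
        if cv == 0:
            return np.ones(n_subjects)

        def sample_cv(sigma: float) -> float:
            s = np.exp(sigma * quantiles)
            return float(s.std(ddof=1) / s.mean())

        from scipy.optimize import brentq

        sigma = brentq(lambda s: sample_cv(s) - cv, 1e-6, 5.0)
        s = np.exp(sigma * quantiles)
        s /= s.mean()
        out = np.empty(n_subjects)
        out[np.argsort(z)] = s
        return out

    s_rms = scales(rms_spread, raw["rms"])
    s_band = scales(band_spread, raw["band"])

    profiles = []
    for i in range(n_subjects):
        g_bb, g_band = _solve_component_gains(
            s_rms[i] ** 2, s_band[i] ** 2, fs, spectral_peak_hz
        )
        profiles.append(
            SubjectProfile(
                gain_per_channel=(g_bb, g_bb),
                band_gain=g_band,
                spectral_peak_hz=spectral_peak_hz,
                seed=subject_seeds[i],
                **profile_kwargs,
            )
        )
    return profiles
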