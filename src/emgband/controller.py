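"""Threshold calibration and the two-channel FLEX/EXT/REST state machine.

Two controller modes share one decision rule and differ only in the feature
monitored per analysis frame:

* ``STFT_BAND`` — mean one-sided spectral magnitude of the 60–80 Hz band of
  each channel (the fixed-bandwidth frequency-domain method);
* ``RMS`` — root mean square of the raw signal over the same windows (the
  conventional time-domain baseline).

Calibration sets each channel's trigger threshold to 50% of the maximum
feature value observed over a calibration recording containing at least one
clear contraction.  Because a single-frame spectral estimate of a stochastic
contraction fluctuates by a factor of ~2, the raw per-frame maximum is not a
usable reference level; the calibration pipeline therefore reads the maximum
off a short moving average of the feature series (0.5 s by default) — the
value an engineer would read off a display — and the running controller
conditions the per-frame feature with a fast-attack / slow-release envelope
follower (instant rise, exponential decay) before thresholding.  The fast
attack preserves onset latency; the slow release bridges single-frame
dropouts that would otherwise fragment a contraction into several events.

At run time a frame is classified FLEX when only the flexor channel exceeds
its threshold, EXT when only the extensor does, REST when neither; when both
exceed, the channel with the larger threshold-normalized ratio wins (a tie
keeps the previous state).  An active state persists until its channel falls
below ``release_fraction`` of the threshold (hysteresis against chattering
around the 50% level), and a state change is committed only after
``debounce_frames`` consecutive agreeing frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import CalibrationError, ConfigurationError, MalformedInputError
from .features import FeatureSeries, rms
from .signal_model import SignalTrace, WindowSpec, frames
from .stft import STFTConfig, band_series, stft

MODES = ("STFT_BAND", "RMS")
DEFAULT_THRESHOLD_FRACTION = 0.5
DEFAULT_DEBOUNCE_FRAMES = 1
DEFAULT_RELEASE_FRACTION = 0.8
DEFAULT_FOLLOWER_RELEASE = 0.3
DEFAULT_CALIBRATION_SMOOTH_S = 1.0

_ACTIONS = {"FLEX": "CLOSE_STEP", "EXT": "OPEN_STEP", "REST": "HOLD"}
_CHANNEL_OF = {"FLEX": "flexor", "EXT": "extensor"}


@dataclass
class TriggerConfig:
    """Controller mode, band, thresholds and decision parameters."""

    mode: str = "STFT_BAND"
    band: tuple[float, float] = (60.0, 80.0)
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    thresholds_mv: dict[str, float] = field(default_factory=dict)
    debounce_frames: int = DEFAULT_DEBOUNCE_FRAMES
    release_fraction: float = DEFAULT_RELEASE_FRACTION
    #: release coefficient of the fast-attack envelope follower applied to the
    #: per-frame feature before thresholding; 1.0 disables the follower.
    follower_release: float = DEFAULT_FOLLOWER_RELEASE

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.threshold_fraction < 1:
            raise ConfigurationError("threshold_fraction must be in (0, 1)")
        if self.debounce_frames < 1:
            raise ConfigurationError("debounce_frames must be >= 1")
        if not 0 < self.release_fraction <= 1:
            raise ConfigurationError("release_fraction must be in (0, 1]")
        if not 0 < self.follower_release <= 1:
            raise ConfigurationError("follower_release must be in (0, 1]")
        if any(v <= 0 for v in self.thresholds_mv.values()):
            raise ConfigurationError("calibrated thresholds must be positive")

    @property
    def calibrated(self) -> bool:
        return {"flexor", "extensor"} <= set(self.thresholds_mv)

    def to_json(self) -> str:
        d = asdict(self)
        d["band"] = list(self.band)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TriggerConfig":
        d = json.loads(text)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass(frozen=True)
class MotionEvent:
    """One classified motion interval; consecutive events tile the timeline."""

    state: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise MalformedInputError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s

    def overlap(self, start_s: float, end_s: float) -> float:
        """Overlap duration with the interval [start_s, end_s]."""
        return max(0.0, min(self.offset_s, end_s) - max(self.onset_s, start_s))


@dataclass(frozen=True)
class MotorCommand:
    """One per-frame motor action (simulated event log of the drive output)."""

    t_s: float
    action: str  # OPEN_STEP | CLOSE_STEP | HOLD


def calibrate(
    calibration_features: dict[str, FeatureSeries],
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    config: TriggerConfig | None = None,
) -> TriggerConfig:
    """Set per-channel thresholds to ``fraction`` × the calibration maximum.

    Each channel's series must contain at least one clear contraction,
    operationalized as max > 3× median; a flat series fails calibration.
    """
    base = config or TriggerConfig()
    thresholds = {}
    for channel, series in calibration_features.items():
        values = np.asarray(series.values if isinstance(series, FeatureSeries) else series, float)
        if values.size == 0:
            raise CalibrationError(f"empty calibration series for channel {channel!r}")
        peak, med = float(values.max()), float(np.median(values))
        if peak <= 3.0 * med or peak <= 0:
            raise CalibrationError(
                f"channel {channel!r}: no clear contraction in calibration recording "
                f"(max {peak:.3g} <= 3x median {med:.3g})"
            )
        thresholds[channel] = fraction * peak
    return TriggerConfig(
        mode=base.mode,
        band=base.band,
        threshold_fraction=fraction,
        thresholds_mv=thresholds,
        debounce_frames=base.debounce_frames,
        release_fraction=base.release_fraction,
        follower_release=base.follower_release,
    )


def smooth_series(series: FeatureSeries, smooth_s: float = DEFAULT_CALIBRATION_SMOOTH_S) -> FeatureSeries:
    """Causal moving average of a feature series over ``smooth_s`` seconds.

    Used on calibration recordings before reading off the maximum, so the
    calibration reference is a display-level average rather than the extreme
    of a noisy single-frame estimate.
    """
    if smooth_s <= 0 or len(series) < 2:
        return series
    dt = float(np.median(np.diff(series.times_s)))
    k = max(1, int(round(smooth_s / dt)))
    cum = np.concatenate([[0.0], np.cumsum(series.values)])
    idx = np.arange(len(series))
    lo = np.maximum(0, idx - k + 1)
    smoothed = (cum[idx + 1] - cum[lo]) / (idx + 1 - lo)
    return FeatureSeries(series.times_s, smoothed, feature_name=series.feature_name,
                         channel=series.channel, units=series.units)


def envelope_follow(values: np.ndarray, release: float = DEFAULT_FOLLOWER_RELEASE) -> np.ndarray:
    """Fast-attack / slow-release follower: instant rise, exponential decay.

    ``y_i = max(x_i, (1-release)·y_{i-1} + release·x_i)``; with release = 1
    the input passes through unchanged.
    """
    if release >= 1.0:
        return np.asarray(values, dtype=float)
    out = np.empty(len(values))
    acc = values[0] if len(values) else 0.0
    for i, x in enumerate(values):
        acc = x if x >= acc else (1.0 - release) * acc + release * x
        out[i] = acc
    return out


def classify_frame(
    flexor_value: float,
    extensor_value: float,
    config: TriggerConfig,
    previous_state: str = "REST",
) -> str:
    """Classify one feature frame given the previously committed state."""
    if not config.calibrated:
        raise ConfigurationError("classify_frame requires a calibrated TriggerConfig")
    thr_f = config.thresholds_mv["flexor"]
    thr_e = config.thresholds_mv["extensor"]

    # hysteresis: an active state holds until its channel releases
    if previous_state == "FLEX" and flexor_value >= config.release_fraction * thr_f:
        return "FLEX"
    if previous_state == "EXT" and extensor_value >= config.release_fraction * thr_e:
        return "EXT"

    above_f = flexor_value >= thr_f
    above_e = extensor_value >= thr_e
    if above_f and above_e:
        ratio_f, ratio_e = flexor_value / thr_f, extensor_value / thr_e
        if ratio_f > ratio_e:
            return "FLEX"
        if ratio_e > ratio_f:
            return "EXT"
        return previous_state
    if above_f:
        return "FLEX"
    if above_e:
        return "EXT"
    return "REST"


def frame_features(
    trace: SignalTrace, config: TriggerConfig, window: WindowSpec | None = None
) -> dict[str, FeatureSeries]:
    """Per-channel feature series for the controller's mode.

    STFT_BAND computes the per-frame 60–80 Hz mean band magnitude; RMS
    computes windowed RMS of the raw signal over identical frames, so the two
    modes are comparable frame for frame.
    """
    window = window or WindowSpec(256, 64)
    out: dict[str, FeatureSeries] = {}
    if config.mode == "STFT_BAND":
        sgram = stft(trace, STFTConfig(window.length_samples, window.hop_samples,
                                       trace.fs, window.taper))
        for name in trace.channel_names:
            out[name] = band_series(sgram, config.band[0], config.band[1], channel=name)
    else:
        times = []
        values: dict[str, list[float]] = {name: [] for name in trace.channel_names}
        for start, win in frames(trace, window):
            times.append(trace.t0 + (start + window.length_samples - 1) / trace.fs)
            for c, name in enumerate(trace.channel_names):
                values[name].append(rms(win[:, c]))
        for name in trace.channel_names:
            out[name] = FeatureSeries(np.array(times), np.array(values[name]),
                                      feature_name="RMS", channel=name)
    return out


def run_controller(
    trace: SignalTrace,
    config: TriggerConfig,
    window: WindowSpec | None = None,
) -> tuple[list[MotionEvent], list[MotorCommand]]:
    """Run the calibrated controller over a two-channel trace.

    Returns the classified motion events (FLEX/EXT/REST intervals tiling the
    timeline from the first frame to the end of the trace) and one motor
    command per frame (CLOSE_STEP during FLEX, OPEN_STEP during EXT, HOLD
    during REST).
    """
    if not config.calibrated:
        raise ConfigurationError("run_controller requires calibrated thresholds")
    missing = {"flexor", "extensor"} - set(trace.channel_names)
    if missing:
        raise ConfigurationError(f"trace is missing channels: {sorted(missing)}")
    feats = frame_features(trace, config, window)
    flexor, extensor = feats["flexor"], feats["extensor"]
    if len(flexor) == 0:
        return [], []
    f_values = envelope_follow(flexor.values, config.follower_release)
    e_values = envelope_follow(extensor.values, config.follower_release)

    committed = "REST"
    pending: str | None = None
    agree = 0
    states, times = [], []
    commands = []
    for t, f_val, e_val in zip(flexor.times_s, f_values, e_values):
        candidate = classify_frame(f_val, e_val, config, committed)
        if candidate == committed:
            pending, agree = None, 0
        elif candidate == pending:
            agree += 1
            if agree >= config.debounce_frames:
                committed, pending, agree = candidate, None, 0
        else:
            pending, agree = candidate, 1
            if agree >= config.debounce_frames:
                committed, pending, agree = candidate, None, 0
        states.append(committed)
        times.append(t)
        commands.append(MotorCommand(t_s=float(t), action=_ACTIONS[committed]))

    end_time = trace.t0 + trace.duration
    events: list[MotionEvent] = []
    run_start = times[0]
    for i in range(1, len(states)):
        if states[i] != states[i - 1]:
            events.append(MotionEvent(states[i - 1], float(run_start), float(times[i])))
            run_start = times[i]
    if end_time > run_start:
        events.append(MotionEvent(states[-1], float(run_start), float(end_time)))
    return events, commands
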