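"""Desk-scale evaluation: reference-statistics reproduction and synthetic
cohort experiments.

Two kinds of evaluation live here:

* ``table3_summary`` — descriptive statistics (mean, SD) over a packaged
  per-subject/per-test table of EMG feature means (RMS, FMEAN, FMED, 60–80 Hz
  band magnitude) from a five-subject wrist-motion feature-selection
  experiment.  Both SD conventions are exposed because published summaries mix
  them: ``population`` divides by n, ``sample`` by n−1.
* Synthetic cohort experiments — ``cohort_experiment`` mirrors the validation
  protocol (per-subject calibration, then repeated flexion/extension trials
  with interleaved rests, scored per trial), and ``variability_report``
  summarizes inter-subject feature variability (mean, SD, CV, span of
  per-subject contraction-level means).

A labeled trial is counted correct when one event of the matching state
overlaps at least half of it and no wrong-state event overlaps it beyond a
small transition-grace tolerance.  The grace (default 20% of the trial
duration) exists because a causal detector necessarily lets each event spill
roughly one analysis window past its label boundary; without it every rest
interval following a contraction would score as wrong.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import (
    MotionEvent,
    TriggerConfig,
    calibrate,
    frame_features,
    run_controller,
    smooth_series,
)
from .errors import MalformedInputError
from .features import FeatureSeries
from .signal_model import SignalTrace, WindowSpec
from .synth_emg import (
    ArtifactSpec,
    EpisodeLabels,
    SubjectProfile,
    make_cohort,
    session_variation,
    synth_episode,
)

FEATURE_COLUMNS = {"RMS": "rms", "FMEAN": "fmean", "FMED": "fmed", "BANDMAG": "bandmag"}


# ---------------------------------------------------------------------------
# reference-table statistics


@dataclass
class Table3Fixture:
    """Per (subject, test) mean/max/min of the four EMG features."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "test"} | {
            f"{col}_{stat}" for col in FEATURE_COLUMNS.values() for stat in ("mean", "max", "min")
        }
        missing = required - set(self.rows.columns)
        if missing:
            raise MalformedInputError(f"fixture missing columns: {sorted(missing)}")
        if len(self.rows) != 10:
            raise MalformedInputError(f"fixture must have 10 rows, got {len(self.rows)}")
        for col in FEATURE_COLUMNS.values():
            bad = (self.rows[f"{col}_min"] > self.rows[f"{col}_mean"]) | (
                self.rows[f"{col}_mean"] > self.rows[f"{col}_max"]
            )
            if bad.any():
                raise MalformedInputError(f"fixture violates min <= mean <= max for {col}")


def load_table3() -> Table3Fixture:
    """Load the packaged feature-selection reference table."""
    with importlib.resources.files("emgband.data").joinpath("table3.csv").open() as fh:
        return Table3Fixture(pd.read_csv(fh))


def table3_summary(
    fixture: Table3Fixture, feature: str, sd_kind: str = "sample"
) -> tuple[float, float]:
    """Mean and SD over the 10 per-test mean values of one feature."""
    if feature not in FEATURE_COLUMNS:
        raise MalformedInputError(f"feature must be one of {sorted(FEATURE_COLUMNS)}")
    if sd_kind not in ("sample", "population"):
        raise MalformedInputError("sd_kind must be 'sample' or 'population'")
    values = fixture.rows[f"{FEATURE_COLUMNS[feature]}_mean"].to_numpy(dtype=float)
    ddof = 1 if sd_kind == "sample" else 0
    return float(values.mean()), float(values.std(ddof=ddof))


# ---------------------------------------------------------------------------
# trial scoring


@dataclass(frozen=True)
class TrialOutcome:
    state: str
    start_s: float
    end_s: float
    correct: bool


def score_episode(
    events: list[MotionEvent],
    labels: EpisodeLabels,
    min_overlap: float = 0.5,
    wrong_overlap_tolerance: float = 0.2,
) -> list[TrialOutcome]:
    """Score each labeled interval as a trial.

    Correct iff exactly one matching-state event overlaps the trial by at
    least ``min_overlap`` of its duration and no wrong-state event overlaps it
    by more than ``wrong_overlap_tolerance`` of its duration.
    """
    outcomes = []
    for start, end, state in labels.intervals:
        dur = end - start
        matching = [ev.overlap(start, end) for ev in events if ev.state == state]
        wrong = [ev.overlap(start, end) for ev in events if ev.state != state]
        n_covering = sum(1 for ov in matching if ov >= min_overlap * dur)
        ok = n_covering == 1 and all(ov <= wrong_overlap_tolerance * dur for ov in wrong)
        outcomes.append(TrialOutcome(state, start, end, ok))
    return outcomes


# ---------------------------------------------------------------------------
# cohort experiment


@dataclass
class AccuracyReport:
    """Per-class and overall recognition accuracy over a simulated cohort."""

    per_class: dict[str, float]  # percent
    n_trials: dict[str, int]
    overall_pct: float
    n_subjects: int
    seed: int
    mode: str = "STFT_BAND"

    def to_dict(self) -> dict:
        return {
            "per_class": dict(self.per_class),
            "n_trials": dict(self.n_trials),
            "overall_pct": self.overall_pct,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "mode": self.mode,
        }


def calibration_labels(contraction_s: float = 2.0, rest_s: float = 1.0) -> EpisodeLabels:
    """Calibration protocol: two contractions per channel with rests."""
    seq = [("REST", rest_s)]
    for _ in range(2):
        seq += [("FLEX", contraction_s), ("REST", rest_s), ("EXT", contraction_s), ("REST", rest_s)]
    return EpisodeLabels.from_sequence(seq)


def trial_labels(trials_per_class: int = 20, contraction_s: float = 4.0,
                 rest_s: float = 4.0) -> EpisodeLabels:
    """Validation protocol: alternating FLEX/EXT trials with interleaved rests."""
    seq = []
    for _ in range(trials_per_class):
        seq += [("REST", rest_s), ("FLEX", contraction_s), ("REST", rest_s), ("EXT", contraction_s)]
    seq.append(("REST", rest_s))
    return EpisodeLabels.from_sequence(seq)


def calibrate_subject(
    profile: SubjectProfile,
    mode: str = "STFT_BAND",
    fs: float = 1100.0,
    window: WindowSpec | None = None,
    base_config: TriggerConfig | None = None,
    smooth_s: float = 1.0,
) -> TriggerConfig:
    """Calibrate per-channel thresholds on a clean recording of this subject.

    The calibration maximum is read off a ``smooth_s`` moving average of the
    feature series (a display-level value), not the raw per-frame extreme.
    """
    base = base_config or TriggerConfig(mode=mode)
    cal_trace = synth_episode(profile, calibration_labels(), ArtifactSpec(), fs=fs)
    feats = frame_features(cal_trace, base, window)
    smoothed = {name: smooth_series(series, smooth_s) for name, series in feats.items()}
    return calibrate(smoothed, fraction=base.threshold_fraction, config=base)


def cohort_experiment(
    n_subjects: int,
    trials_per_class: int = 20,
    mode: str = "STFT_BAND",
    seed: int = 0,
    artifacts: ArtifactSpec | None = None,
    fs: float = 1100.0,
    window: WindowSpec | None = None,
    contraction_s: float = 4.0,
    rest_s: float = 4.0,
) -> AccuracyReport:
    """Calibrate and run the controller for each simulated subject, then score.

    Each subject is calibrated on a clean recording, then classified on a
    fresh labeled episode recorded in a *new session* (session drift applied)
    with ``trials_per_class`` FLEX and EXT trials and interleaved REST
    trials; accuracy is pooled over all subjects' trials.
    """
    profiles = make_cohort(n_subjects, seed=seed, fs=fs)
    labels = trial_labels(trials_per_class, contraction_s, rest_s)
    correct = {"FLEX": 0, "EXT": 0, "REST": 0}
    totals = {"FLEX": 0, "EXT": 0, "REST": 0}
    for i, profile in enumerate(profiles):
        config = calibrate_subject(profile, mode=mode, fs=fs, window=window)
        test_profile = session_variation(profile, session_seed=(profile.seed + 1) % (2**31), fs=fs)
        trace = synth_episode(test_profile, labels, artifacts, fs=fs)
        events, _ = run_controller(trace, config, window)
        for outcome in score_episode(events, labels):
            totals[outcome.state] += 1
            correct[outcome.state] += int(outcome.correct)
    per_class = {s: 100.0 * correct[s] / totals[s] for s in totals if totals[s]}
    n_all = sum(totals.values())
    overall = 100.0 * sum(correct.values()) / n_all if n_all else 0.0
    return AccuracyReport(per_class=per_class, n_trials=totals, overall_pct=overall,
                          n_subjects=n_subjects, seed=seed, mode=mode)


def transfer_experiment(
    n_subjects: int = 20,
    trials_per_class: int = 5,
    mode: str = "STFT_BAND",
    seed: int = 0,
    artifacts: ArtifactSpec | None = None,
    fs: float = 1100.0,
    window: WindowSpec | None = None,
) -> tuple[float, float]:
    """Accuracy with own calibration vs. thresholds transferred from another
    subject.

    Each subject is calibrated on their own clean recording; the transfer
    condition reuses the previous cohort member's thresholds unchanged (the
    no-onsite-calibration scenario).  Returns
    ``(own_accuracy_pct, transfer_accuracy_pct)`` pooled over all trials.
    """
    if n_subjects < 2:
        raise MalformedInputError("transfer_experiment needs >= 2 subjects")
    profiles = make_cohort(n_subjects, seed=seed, fs=fs)
    configs = [calibrate_subject(p, mode=mode, fs=fs, window=window) for p in profiles]
    labels = trial_labels(trials_per_class)
    n_correct = {"own": 0, "transfer": 0}
    n_total = 0
    for i, profile in enumerate(profiles):
        test_profile = session_variation(profile, session_seed=(profile.seed + 1) % (2**31), fs=fs)
        trace = synth_episode(test_profile, labels, artifacts, fs=fs)
        for condition, config in (("own", configs[i]), ("transfer", configs[i - 1])):
            events, _ = run_controller(trace, config, window)
            outcomes = score_episode(events, labels)
            n_correct[condition] += sum(o.correct for o in outcomes)
        n_total += len(labels.intervals)
    return 100.0 * n_correct["own"] / n_total, 100.0 * n_correct["transfer"] / n_total


# ---------------------------------------------------------------------------
# inter-subject variability


def contraction_feature_means(
    profile: SubjectProfile,
    fs: float = 1100.0,
    window: WindowSpec | None = None,
    n_contractions: int = 4,
    contraction_s: float = 2.0,
) -> dict[str, float]:
    """Per-subject contraction-level mean of RMS and 60–80 Hz band magnitude.

    Simulates a clean episode of repeated flexions and averages each feature
    over frames whose window lies entirely inside a contraction interval.
    """
    window = window or WindowSpec(256, 64)
    seq = [("REST", 1.0)]
    for _ in range(n_contractions):
        seq += [("FLEX", contraction_s), ("REST", 1.0)]
    labels = EpisodeLabels.from_sequence(seq)
    trace = synth_episode(profile, labels, ArtifactSpec(), fs=fs)

    means: dict[str, float] = {}
    for mode, feature in (("RMS", "RMS"), ("STFT_BAND", "BANDMAG")):
        series = frame_features(trace, TriggerConfig(mode=mode), window)["flexor"]
        keep = np.zeros(len(series), dtype=bool)
        win_s = window.length_samples / fs
        for start, end in labels.active_intervals("FLEX"):
            keep |= (series.times_s >= start + win_s) & (series.times_s <= end)
        if not keep.any():
            raise MalformedInputError("no frames fully inside a contraction interval")
        means[feature] = float(series.values[keep].mean())
    return means


def variability_report(cohort_features: dict[str, list[float]]) -> pd.DataFrame:
    """Across-subject mean, SD, CV and span of per-subject feature means.

    ``cohort_features`` maps a feature name to one contraction-level mean per
    subject (at least 2 subjects).
    """
    rows = {}
    for feature, per_subject in cohort_features.items():
        values = np.asarray(per_subject, dtype=float)
        if values.size < 2:
            raise MalformedInputError("variability_report needs >= 2 subjects")
        mean = values.mean()
        sd = values.std(ddof=1)
        rows[feature] = {
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean else np.nan,
            "span": values.max() - values.min(),
            "n_subjects": values.size,
        }
    return pd.DataFrame(rows).T


def measure_cohort_variability(
    n_subjects: int = 50,
    rms_spread: float = 0.46,
    band_spread: float = 0.43,
    seed: int = 0,
    fs: float = 1100.0,
    n_contractions: int = 3,
) -> pd.DataFrame:
    """Simulate a cohort and report the realized feature variability."""
    profiles = make_cohort(n_subjects, rms_spread=rms_spread, band_spread=band_spread,
                           seed=seed, fs=fs)
    per_feature: dict[str, list[float]] = {"RMS": [], "BANDMAG": []}
    for profile in profiles:
        means = contraction_feature_means(profile, fs=fs, n_contractions=n_contractions)
        for feature, value in means.items():
            per_feature[feature].append(value)
    return variability_report(per_feature)
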