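import numpy as np
import pytest

from emgband import (
    ArtifactSpec,
    CalibrationError,
    ConfigurationError,
    EpisodeLabels,
    FeatureSeries,
    SignalTrace,
    SubjectProfile,
    TriggerConfig,
    calibrate,
    calibrate_subject,
    classify_frame,
    envelope_follow,
    run_controller,
    smooth_series,
    synth_episode,
    transfer_experiment,
)

FS = 1100.0


def series(values, name="BANDMAG"):
    values = np.asarray(values, dtype=float)
    return FeatureSeries(np.arange(len(values), dtype=float), values, feature_name=name)


class TestCalibrate:
    def test_threshold_is_half_of_maximum(self):
        feats = {"flexor": series([0.1, 0.2, 10.0, 0.3]),
                 "extensor": series([0.1, 8.0, 0.2, 0.1])}
        config = calibrate(feats, fraction=0.5)
        assert config.thresholds_mv["flexor"] == pytest.approx(5.0)
        assert config.thresholds_mv["extensor"] == pytest.approx(4.0)

    def test_fraction_one_keeps_maximum(self):
        config = calibrate({"flexor": series([0.0, 0.0, 0.0, 10.0]),
                            "extensor": series([0.0, 0.0, 0.0, 10.0])}, fraction=0.99)
        assert config.thresholds_mv["flexor"] == pytest.approx(9.9)

    def test_flat_series_fails(self):
        with pytest.raises(CalibrationError):
            calibrate({"flexor": series([2.0, 2.0, 2.0, 2.0]),
                       "extensor": series([0.0, 9.0])})

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            TriggerConfig(mode="WAVELET")
        with pytest.raises(ConfigurationError):
            TriggerConfig(threshold_fraction=1.5)
        with pytest.raises(ConfigurationError):
            TriggerConfig(thresholds_mv={"flexor": -1.0})

    def test_json_round_trip(self):
        config = TriggerConfig(mode="RMS", thresholds_mv={"flexor": 3.0, "extensor": 4.0})
        back = TriggerConfig.from_json(config.to_json())
        assert back == config


class TestClassifyFrame:
    @pytest.fixture
    def config(self):
        return TriggerConfig(thresholds_mv={"flexor": 5.0, "extensor": 5.0})

    def test_antagonist_logic(self, config):
        assert classify_frame(6.0, 1.0, config, "REST") == "FLEX"
        assert classify_frame(1.0, 6.0, config, "REST") == "EXT"
        assert classify_frame(0.0, 0.0, config, "REST") == "REST"

    def test_ratio_tie_break_when_both_exceed(self, config):
        assert classify_frame(7.0, 6.0, config, "REST") == "FLEX"  # 1.4 vs 1.2
        assert classify_frame(6.0, 7.0, config, "REST") == "EXT"
        assert classify_frame(6.0, 6.0, config, "EXT") == "EXT"  # tie keeps previous

    def test_hysteresis_holds_until_release(self, config):
        # release_fraction 0.8: active FLEX persists down to 4.0
        assert classify_frame(4.5, 0.0, config, "FLEX") == "FLEX"
        assert classify_frame(3.9, 0.0, config, "FLEX") == "REST"
        assert classify_frame(4.5, 0.0, config, "REST") == "REST"  # no re-entry below 5

    def test_uncalibrated_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_frame(1.0, 1.0, TriggerConfig(), "REST")


class TestConditioning:
    def test_envelope_follow_attacks_instantly_and_decays(self):
        out = envelope_follow(np.array([0.0, 10.0, 0.0, 0.0]), release=0.4)
        assert out[1] == 10.0
        assert out[2] == pytest.approx(6.0)
        assert out[3] == pytest.approx(3.6)

    def test_envelope_follow_identity_at_release_one(self):
        x = np.array([3.0, 1.0, 2.0])
        assert np.array_equal(envelope_follow(x, release=1.0), x)

    def test_smooth_series_flattens_spikes(self):
        s = series([1.0] * 20 + [10.0] + [1.0] * 20)
        smoothed = smooth_series(s, smooth_s=5.0)  # 5-sample boxcar at 1 Hz spacing
        assert smoothed.values.max() < 4.0
        assert smoothed.values.max() > 1.0


class TestRunController:
    def test_single_flex_event_with_bounded_latency(self, flex_episode,
                                                    calibrated_stft_config):
        trace, labels = flex_episode
        events, commands = run_controller(trace, calibrated_stft_config)
        flex = [e for e in events if e.state == "FLEX"]
        assert len(flex) == 1
        assert not [e for e in events if e.state == "EXT"]
        (start, _), = labels.active_intervals("FLEX")
        assert 0 < flex[0].onset_s - start <= 0.35

    def test_commands_mirror_states(self, flex_episode, calibrated_stft_config):
        trace, _ = flex_episode
        events, commands = run_controller(trace, calibrated_stft_config)
        assert all(c.action in {"OPEN_STEP", "CLOSE_STEP", "HOLD"} for c in commands)
        during_flex = [c for c in commands
                       if any(e.onset_s <= c.t_s < e.offset_s and e.state == "FLEX"
                              for e in events)]
        assert during_flex and all(c.action == "CLOSE_STEP" for c in during_flex)

    def test_zero_signal_gives_single_rest_event(self, calibrated_stft_config):
        trace = SignalTrace(np.zeros((int(2 * FS), 2)), FS,
                            channel_names=("flexor", "extensor"))
        events, commands = run_controller(trace, calibrated_stft_config)
        assert [e.state for e in events] == ["REST"]
        assert all(c.action == "HOLD" for c in commands)

    def test_unreachable_thresholds_give_no_motion(self, flex_episode):
        trace, _ = flex_episode
        config = TriggerConfig(thresholds_mv={"flexor": 1e9, "extensor": 1e9})
        events, _ = run_controller(trace, config)
        assert {e.state for e in events} == {"REST"}

    def test_determinism(self, flex_episode, calibrated_stft_config):
        trace, _ = flex_episode
        a, _ = run_controller(trace, calibrated_stft_config)
        b, _ = run_controller(trace, calibrated_stft_config)
        assert a == b

    def test_missing_channel_rejected(self, calibrated_stft_config):
        trace = SignalTrace(np.zeros((600, 1)), FS, channel_names=("flexor",))
        with pytest.raises(ConfigurationError):
            run_controller(trace, calibrated_stft_config)

    def test_events_tile_timeline(self, flex_episode, calibrated_stft_config):
        trace, _ = flex_episode
        events, _ = run_controller(trace, calibrated_stft_config)
        for prev, nxt in zip(events, events[1:]):
            assert prev.offset_s == pytest.approx(nxt.onset_s)
        assert events[-1].offset_s == pytest.approx(trace.duration)

    def test_raising_threshold_never_extends_triggered_time(self, flex_episode,
                                                            calibrated_stft_config):
        """Total FLEX duration is monotone non-increasing in the flexor threshold."""
        trace, _ = flex_episode
        base = calibrated_stft_config.thresholds_mv
        durations = []
        for factor in (1.0, 1.25, 1.6, 2.5):
            config = TriggerConfig(
                thresholds_mv={"flexor": base["flexor"] * factor,
                               "extensor": base["extensor"]},
            )
            events, _ = run_controller(trace, config)
            durations.append(sum(e.duration for e in events if e.state == "FLEX"))
        assert all(a >= b - 1e-12 for a, b in zip(durations, durations[1:]))


class TestRobustness:
    def test_band_mode_ignores_rest_artifacts_rms_mode_does_not(self, default_profile):
        """Artifacts at rest: no false triggers in band mode, false triggers in RMS mode."""
        labels = EpisodeLabels.from_sequence([("REST", 8.0)])
        art = ArtifactSpec.standard(default_profile.contraction_mv)
        stft_false = rms_false = 0
        for seed in range(5):
            profile = SubjectProfile(seed=seed)
            trace = synth_episode(profile, labels, art)
            for mode in ("STFT_BAND", "RMS"):
                config = calibrate_subject(profile, mode=mode, fs=FS)
                events, _ = run_controller(trace, config)
                n_false = sum(1 for e in events if e.state != "REST")
                if mode == "STFT_BAND":
                    stft_false += n_false
                else:
                    rms_false += n_false > 0
        assert stft_false == 0
        assert rms_false >= 3  # majority of episodes

    def test_transfer_stability_contrast(self):
        """Band-mode thresholds transfer across subjects; RMS collapses in noise.

        Clean conditions: band-mode accuracy with a donor subject's thresholds
        stays within 10 points of own calibration.  With rest artifacts the
        band controller is unaffected while the RMS controller loses far more
        accuracy relative to its clean own-calibration baseline.
        """
        stft_own, stft_transfer = transfer_experiment(
            n_subjects=10, trials_per_class=3, mode="STFT_BAND", seed=0)
        assert stft_own - stft_transfer < 10.0

        art = ArtifactSpec.standard(400.0)
        _, stft_noisy_transfer = transfer_experiment(
            n_subjects=10, trials_per_class=3, mode="STFT_BAND", seed=0, artifacts=art)
        rms_own_clean, _ = transfer_experiment(
            n_subjects=10, trials_per_class=3, mode="RMS", seed=0)
        _, rms_noisy_transfer = transfer_experiment(
            n_subjects=10, trials_per_class=3, mode="RMS", seed=0, artifacts=art)
        stft_loss = stft_own - stft_noisy_transfer
        rms_loss = rms_own_clean - rms_noisy_transfer
        assert rms_loss > stft_loss + 10.0
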