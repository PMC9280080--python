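# emgband

Fixed-bandwidth frequency-domain myoelectric triggering, at desk scale.

Surface EMG (sEMG) is the standard control signal for myoelectric assistive
devices: a contraction of the flexor carpi ulnaris or extensor carpi radialis
longus raises the electrical activity recorded over the muscle, and a
threshold on some feature of that activity opens or closes a robotic hand.
The conventional feature is the windowed RMS of the raw voltage — simple, but
it integrates *everything*: powerline hum, low-frequency motion artifact,
broadband noise. Those contaminations inflate the resting signal, vary
between users and sessions, and force per-user, per-session threshold
calibration.

This package implements the alternative that `emgband` is named for: monitor
only the voltage magnitude of a fixed **60–80 Hz** spectral band, the band in
which forearm-muscle contraction energy is most prominent (spectral peak near
70 Hz), via a streaming 256-point short-time Fourier transform at an
1,100 Hz sampling rate. Mains interference (50/60 Hz), motion artifact
(< 20 Hz) and most broadband noise fall outside or barely touch this band, so
the band magnitude at rest is essentially unchanged by them while whole-signal
RMS is not — the band feature is *denoised by construction*, and one 50 %-of-
maximum threshold survives transfer across users.

The package contains:

* `signal_model` — `SignalTrace` container, CSV/WAV I/O, causal sliding
  windows;
* `synth_emg` — a seeded two-channel (flexor/extensor) synthetic sEMG
  generator with the spectral shape, inter-subject variability, session
  drift, and artifact structure described above;
* `features` — RMS, rectified-integrated EMG (RIEMG), periodogram PSD,
  median/mean frequency (FMED/FMEAN), fixed-band magnitude;
* `stft` — batch and streaming STFT (one-sided, amplitude-normalized so
  thresholds are in input mV);
* `controller` — threshold calibration (50 % of the calibration maximum) and
  the two-channel FLEX/EXT/REST state machine with hysteresis and debounce,
  in both STFT-band and RMS-baseline modes;
* `evaluation` — trial scoring, cohort accuracy experiments, inter-subject
  variability summaries, and the packaged per-subject feature reference
  table.

## Core quantities

For a window \(x_0,\dots,x_{N-1}\) at sampling rate \(f_s\):

* RMS \(= \sqrt{\tfrac{1}{N}\sum_i x_i^2}\);  RIEMG \(= \tfrac{1}{f_s}\sum_i |x_i|\)
* STFT frame: \(X_k = \sum_n g_n x_n e^{-2\pi i kn/N}\) with Hann taper
  \(g\), one-sided magnitude \(2|X_k|/\sum_n g_n\) (bin spacing
  \(f_s/N = 4.3\) Hz at the 1,100 Hz / 256-point defaults)
* Band magnitude = mean magnitude over bins with center frequency in
  [60, 80] Hz (bins 14–18 at defaults)
* FMED: frequency splitting the PSD into equal halves; FMEAN
  \(= \sum_k I_k f_k / \sum_k I_k\)
* Trigger rule: channel fires when its band magnitude (or RMS) exceeds
  50 % of the maximum seen during calibration; FLEX/EXT decided by which
  channel exceeds its threshold (threshold-normalized ratio breaks ties),
  with hysteresis (release at 0.8× threshold) and a 1-frame debounce.

## Worked example

```python
import emgband as eb

profile = eb.SubjectProfile(seed=0)                    # one synthetic subject
labels = eb.EpisodeLabels.from_sequence(
    [("REST", 1.0), ("FLEX", 2.0), ("REST", 1.0)])
trace = eb.synth_episode(profile, labels, None, fs=1100.0)

config = eb.calibrate_subject(profile, mode="STFT_BAND")
print({k: round(v, 1) for k, v in config.thresholds_mv.items()})
events, commands = eb.run_controller(trace, config)
for e in events:
    print(f"{e.state:4s} {e.onset_s:6.3f} -> {e.offset_s:6.3f} s")
```

prints

```
{'flexor': 122.4, 'extensor': 91.5}
REST  0.232 ->  1.279 s
FLEX  1.279 ->  3.199 s
REST  3.199 ->  4.000 s
```

The thresholds are 50 % of the smoothed calibration maxima in mV. The single
FLEX event starts 0.279 s after the labeled 1.0 s onset — the analysis window
(233 ms) plus one hop — and covers the labeled contraction; the controller
emits one `CLOSE_STEP` command per frame inside it.

The same pipeline from a shell:

```bash
emgband simulate --seed 0 --duration 8 --out episode.csv --labels labels.json
emgband stft --in episode.csv --band 60:80 --out band.csv
emgband table3 --feature fmean --sd-kind population   # FMEAN: mean=71.06 sd=5.43
emgband evaluate --cohort 5 --trials 5 --mode stft --seed 0
```

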