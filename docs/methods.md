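# Methods

This note documents the models, parameters and numerical choices behind
`emgband`: what the synthetic sEMG generator does and does not emulate, how
the fixed-band trigger is built, and what the shipped experiments do and do
not demonstrate.

## Signal model and conventions

A `SignalTrace` is a uniformly sampled multi-channel voltage series in
millivolts. All windowing is **causal**: a frame of length `L` starting at
sample `s` carries the timestamp of its last sample, `(s + L − 1)/fs`, the
earliest moment a streaming device could hold the complete window. Frame
counts follow `floor((n − L)/h) + 1` for hop `h`; trailing partial windows
are discarded.

The embedded operating point is the package default everywhere: sampling
rate 1,100 Hz (comfortably above twice the ~500 Hz upper edge of surface-EMG
content), 256-point FFT (bin spacing 4.30 Hz), hop 64 samples (58 ms), Hann
taper. One-sided STFT magnitudes are normalized by `2/Σg` (`1/Σg` at DC and
Nyquist) so an on-bin unit sinusoid reads 1 mV and calibrated thresholds are
in input-voltage units. The Hann taper matters: its sidelobes keep a 50 Hz
mains component from leaking appreciably into the 60–80 Hz band, which a
rectangular window would not.

## Synthetic sEMG generator

The generator stands in for two-channel forearm recordings
(flexor/extensor). It reproduces the *statistical* structure a fixed-band
trigger cares about, not motor-unit physiology:

* **Contraction carrier.** Zero-mean Gaussian process built from two
  unit-RMS components: white noise through a 3rd-order Butterworth band-pass
  (35–110 Hz), plus white noise through a 2nd-order resonator
  (`iirpeak`, Q = 5) at the subject's spectral peak (default 70 Hz)
  carrying 35 % of the power. The mixture has ≥ 95 % of its power in
  30–200 Hz, a modal periodogram bin in 60–80 Hz, and a mean frequency in
  the high 70s of Hz. Filter transients are flushed with a discarded 1 s
  lead-in.
* **Activation envelope.** Raised-cosine rise/fall ramps of 100 ms inside
  each labeled contraction interval, so onset latency of a downstream
  detector is well defined. Nominal contraction RMS is 400 mV; the resting
  floor is a continuous carrier of the same spectral shape at 40 mV.
* **Antagonist structure.** During FLEX the flexor channel carries the
  contraction process and the extensor stays at rest level plus a 10 %
  cross-talk fraction, and symmetrically for EXT.
* **Artifacts** (additive, amplitudes given as RMS): a powerline sinusoid
  (50 Hz default — deliberately outside the monitored band; 60 Hz is
  selectable), a < 20 Hz motion artifact (4th-order low-passed noise), and
  optional white broadband noise. The standard contamination used in the
  robustness experiments is powerline at 0.3× and motion artifact at 0.5×
  the nominal contraction RMS; these are assumptions of this package, not
  measured values.
* **Determinism.** One integer seed fully determines an episode;
  per-channel and per-component streams are spawned from a
  `SeedSequence`, so changing one artifact cannot shift another
  component's realization.

### Inter-subject and inter-session variability

Cohorts are drawn so that the across-subject coefficient of variation (CV)
of contraction RMS is 0.46 and of the 60–80 Hz band magnitude 0.43 — the
CVs of the packaged per-subject reference table. Because both features
would scale identically under a single amplitude gain, each subject carries
two gains: one on the broadband component and one on the resonant
component. Target scales for (RMS, band magnitude) are drawn as correlated
log-normals (rank correlation ≈ 0.8, shared "subject strength" factor) and
converted to component gains by solving a 2×2 linear system whose
coefficients are the components' total and in-band power fractions,
computed from the actual filter frequency responses. Marginals are sampled
by midpoint-stratified quantiles (Latin-hypercube style) with the
log-normal σ solved so the *sample* CV of the cohort equals the requested
spread; without stratification the heavy-tailed CV estimator is too noisy
at cohort sizes of 20–50 for any reproducible statement.

Session-to-session drift is modeled the same way
(`session_variation`): log-normal session factors with CV 0.15 for the RMS
scale and 0.05 for the band scale, reflecting that whole-signal amplitude
drifts appreciably between recording sessions while the fixed-band
magnitude is comparatively stable. Cohort experiments calibrate on one
session and test on another.

What the generator does **not** emulate: motor-unit action-potential
trains and recruitment, fatigue-induced spectral compression, electrode
lift-off, impedance changes, or nonstationary mains interference. Passing
tests therefore demonstrate the *mechanism* of fixed-band denoising and
threshold transfer under the stated statistical structure, not performance
on any particular human recording.

## Features

* `riemg`: rectangular-rule integral of |x|, i.e. `Σ|x_i|/fs` (mV·s) — the
  sampled-data version of a rectify-and-integrate sensor stage
  (`rectify_integrate` provides the streaming first-order-low-pass
  equivalent with DC gain 1).
* `psd`: tapered one-sided periodogram of the window; normalization is
  chosen so `Σ power · Δf` equals the mean square of the *tapered* signal
  (Parseval in the analysis domain).
* `fmed`: half-power frequency with each bin's mass spread uniformly over
  its bin-width interval and linear interpolation inside the crossing bin —
  a single occupied bin returns exactly its center frequency.
* `fmean`: linear-intensity-weighted mean frequency. A dB-weighted variant
  exists behind a flag but is not the default: dB weights depend on an
  arbitrary reference level and break scale invariance.
* `band_magnitude`: the **mean** (not sum) of magnitudes over bins whose
  center lies in the closed band [60, 80] Hz. The mean makes the value
  insensitive to FFT length, so one threshold works across window
  configurations. At the defaults the band comprises bins 14–18
  (60.16–77.34 Hz).

## Trigger controller

Both modes share the decision machinery and differ only in the per-frame
feature: the 60–80 Hz band magnitude (STFT_BAND) or the windowed RMS of the
raw signal over identical frames (RMS baseline).

**Calibration.** Per channel, threshold = 50 % of the maximum feature value
over a calibration recording containing clear contractions (precondition:
max > 3× median, otherwise calibration fails — which genuinely happens for
weak subjects in heavy noise in RMS mode). A raw single-frame spectral
estimate of a stochastic signal fluctuates by roughly a factor two
(CV ≈ 0.31, max/mean ≈ 2 over a minute), so the *raw* maximum is not a
usable reference; the calibration pipeline reads the maximum off a 1.0 s
moving average of the feature series — the value one would read off a
display during a held contraction.

**Runtime conditioning.** Before thresholding, the per-frame feature passes
through a fast-attack / slow-release envelope follower
(`y = max(x, 0.7·y_prev + 0.3·x)`): rises are instantaneous (preserving
onset latency), single-frame dropouts decay slowly enough not to fragment a
contraction into several events. Chosen by simulation over the controller
design grid; without it trial accuracy saturates near 85 %, with it near
99 %.

**Decision rule.** FLEX if only the flexor channel exceeds its threshold,
EXT if only the extensor, REST if neither; if both exceed, the larger
value/threshold ratio wins and an exact tie keeps the previous state. An
active state persists until its channel falls below 0.8× threshold
(hysteresis), and any state change commits only after 1 frame of agreement
(debounce, configurable). With the default geometry a step onset is
detected within `(256 + 64)/1100 ≈ 291 ms` of signal time, inside a 349 ms
budget; measured delay for an on-bin tone step is ≈ 105 ms because partial
windows already carry enough band energy.

## Evaluation

**Reference table.** The packaged CSV holds per-subject/per-test means,
maxima and minima of the four features from a five-subject wrist-motion
feature-selection experiment. `table3_summary` reports mean and SD over the
10 per-test means; both SD conventions are exposed (`population` = ÷n,
`sample` = ÷(n−1)) because published summaries mix them — the mean
frequency statistic (71.06 ± 5.43 Hz) matches the population convention and
the band-magnitude statistic (39.8 ± 17.1 mV) the sample convention.

**Trial scoring.** Episodes follow the validation protocol: alternating
4 s FLEX and EXT trials separated by 4 s rests, 20 of each per subject by
default. A trial is correct when exactly one matching-state event overlaps
at least half of it and no wrong-state event overlaps more than 20 % of it.
The 20 % transition grace exists because a causal detector necessarily
lets each event spill roughly one analysis window past its label; a strict
no-overlap rule would fail every rest that follows a contraction on
latency alone. This operationalization (including both percentages) is a
design choice of this package.

**Experiments.** `cohort_experiment` calibrates each subject on a clean
recording and scores a fresh session; at 20 subjects × 20 trials per class
the clean STFT-mode accuracy is ≈ 100 %. The denoising contrast runs 20
rest-only episodes with the standard artifacts: band magnitude at rest
changes < 1 % while whole-signal RMS rises ≈ 5×, and the band-mode
controller emits zero false events while the clean-calibrated RMS
controller false-triggers in essentially every episode.
`transfer_experiment` reuses a donor subject's thresholds unchanged: in
clean conditions band-mode accuracy stays within 10 points of own
calibration, and under the standard artifacts the band controller is
numerically unaffected while the RMS controller collapses — the two modes'
transfer losses differ by ≈ 60 points. Under clean conditions alone the two
modes transfer almost equally well, because both features scale with
per-subject gains of nearly equal prescribed CV; the fixed-band advantage
is specifically an artifact-rejection property, and the experiments state
it that way.

**Problem sizes.** Cohorts of 20 (accuracy, transfer) and 50 (variability
recovery), 20 seeded episodes for spectral and robustness checks, 4 s
trials: these sizes keep every experiment deterministic, seeded, and
runnable on a laptop in seconds while leaving comfortable statistical
margins.

## Known limitations

* The generator's Gaussian carrier underestimates the impulsive character
  of real low-force EMG; per-frame feature CVs may differ on real data, and
  the follower/hysteresis constants may need retuning there.
* The 60–80 Hz band and the ≈ 70 Hz peak are taken as given for the target
  muscle group; other muscles or electrode placements shift both.
* A 60 Hz mains environment places interference *inside* the monitored
  band; the artifact-separation results hold for mains outside the band
  (50 Hz default here, or a 60 Hz notch upstream).
* Accuracy percentages from synthetic cohorts characterize the algorithm
  under this generator's assumptions; they are not predictions of
  human-subject performance.
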