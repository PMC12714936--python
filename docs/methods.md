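# Methods

This note records the models behind `abrnirs`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Signal models

### Click-evoked brainstem response (EEG)

Each click evokes a stereotyped template: the sum of three Gaussian
bumps (FWHM 0.4 ms) at the wave I/III/V latencies for that stimulus
intensity. Latency grows and amplitude shrinks as the click gets
quieter; the defaults put wave V at 6.1/6.7/7.5 ms and 0.50/0.30/0.125
µV for 90/70/50 dB SPL, inside the clinical scoring windows and with the
~0.3 ms-per-10-dB latency shift seen in adult ABR. At the 81.9 Hz
repetition rate the 12.21-ms inter-onset interval slightly exceeds the
12-ms epoch, so consecutive responses just avoid overlap; overlapping
responses, when they occur, sum linearly. White sensor noise (default sd
5 µV) gives a per-click wave-V SNR near 0.1, the regime where only
~1000-trial averages reveal the response — the reason ABR is an
averaging technique at all.

The simulator runs at 16 kHz. Clinical ABR hardware often digitizes
far slower, but a 100–3000 Hz analysis band and 0.1-ms stimuli require a
rate comfortably above 6 kHz; the simulator favors physical consistency
over mimicking any particular amplifier.

### Block-design hemodynamics (fNIRS)

Raw intensity per channel is

    I_ch(t) = baseline · (1 + β_ch·r(t) + systemic(t) + drift·t + ε(t))

where `r(t)` is a unit-peak gamma-density kernel whose mode sits
`trough_latency` (default 12 s, midpoint of the observed 10–15 s trough)
after each warble onset and which returns to baseline by
`response_duration` (default 30 s; the gamma shape/scale are solved from
mode m and sd (duration − m)/3). Channel betas default to heterogeneous
fractional dips of 0.8–2.3% (negative: the task darkens the channel).
`systemic(t)` is shared across channels — sinusoids at 1.1 Hz (cardiac),
0.3 Hz (respiratory) and 0.1 Hz (vasomotor/Mayer) with seed-drawn phases
and fractional amplitudes 0.5/0.5/0.8% — plus a linear drift of
10⁻⁴/s and white noise of sd 0.5%. Effective sample rate is 10 Hz.

The paired chromophore recording inverts the optical sign: ΔHbT =
−hbt_scale·(β_ch·r + systemic) µM (an intensity decrease is an HbT
increase), with ΔHbO = 1.4·ΔHbT and ΔHbR = −0.4·ΔHbT, so HbO rises,
HbR dips more weakly, and ΔHbO + ΔHbR ≡ ΔHbT exactly. The generator is
single-wavelength by design: it produces one intensity trace per
channel, not a two-wavelength Beer–Lambert reconstruction.

Breath holds add the *same* slow Gaussian excursion (default −3% over
~15 s) to every channel — a global artifact that the spatial ANOVA, by
construction, should not attribute to localized activity.

All generators are pure functions of (parameters, seed).

## Analysis choices

* **Filter.** 4th-order Butterworth 100–3000 Hz applied
  forward-backward: latency scoring must not be biased by group delay.
* **Baseline.** A 0.5-s baseline cannot live inside a 12-ms epoch;
  baseline statistics come from the 0.5 s of continuous filtered signal
  preceding each intensity block. The stored baseline sd is divided by
  √n so the SNR of an *average* is measured against the residual noise
  actually present in that average; with 1000 sweeps this lands 90-dB
  SNRs near 5 and preserves the monotone intensity dependence. At low
  amplitudes the measured SNR floors out near the expected maximum of
  the residual noise (the peak picker finds *some* extremum), a property
  worth remembering when reading small SNRs.
* **Peak scoring.** `scipy.signal.find_peaks` with the 0.08 height and
  2-ms distance criteria applied globally, then windows assigned; the
  tallest qualifying peak per window wins, ties to the earlier latency.
  Qualifying peaks outside all windows are reported as extra peaks, and
  absence of a wave is a result, not an error.
* **Cross-modal lag grid.** Both waveforms are linearly interpolated to
  256 Hz before lagged correlation, quantizing lags to 3.906 ms; a
  minimum overlap of 3 grid points excludes the degenerate two-point
  lags at the window edge.
* **GLM.** Per channel and subject: OLS of the fractional intensity
  change on [intercept, centered linear drift, task regressor], the
  regressor being 2-s boxcars convolved with the negative gamma kernel
  and normalized to a −1 trough, so the beta estimates the fractional
  dip amplitude directly. Group inference is a one-sample t across
  subject betas per channel (summary-statistics approach), FDR-corrected
  over channels. Single-subject OLS p-values are *conservative* under
  the autocorrelated systemic noise and are reported for diagnostics,
  not inference.
* **Cross-correlation.** Reported against a positive-going copy of the
  task regressor so a task-locked intensity decrease produces a negative
  peak; both the normalized coefficient and the unnormalized
  cross-covariance are returned, since the latter's magnitude depends on
  segment length and units.
* **PCA.** Uncentered SVD of the epoch matrix. With per-time-point
  centering PC1 could only reflect epoch-to-epoch amplitude deviations,
  and for realistic epoch counts the noise eigenvalue edge swamps that
  variance; uncentered, a recurring evoked pattern dominates PC1, which
  is the behavior the battery relies on ("PC1 matches the averaged
  response"). Explained fractions are squared singular values normalized
  to sum to one.
* **Stimulation-vs-silence contrast.** Silence segments are the 2-s
  windows immediately preceding each warble onset, length-matched to the
  stimulation segments. Each (stim, silence) pair gets a Pearson r and a
  two-sample t-test on the raw samples; matrices are averaged over
  channels and subjects, marked at |r| > 0.25 and p < 0.05, and the
  p-value histogram uses 0.005-wide bins with an edge exactly at 0.05.
* **Spatial ANOVA.** One-way repeated-measures F via `pingouin` with
  df = (C−1, (C−1)(S−1)); no sphericity correction by default
  (Greenhouse–Geisser optional). Post-hoc all-pairs paired t-tests are
  Holm-corrected. A design with literally zero between-channel variation
  returns F = 0, p = 1 rather than 0/0.
* **Warble internals.** The warble waveform is an alternating-polarity
  pulse train, default 100 pulses/s: the alternation drives the
  diaphragm in both directions and makes the stimulus exactly zero-mean;
  the audible rate is a free parameter. Click intensity blocks
  concatenate with a configurable gap (default 0 s; the study runners
  use 1-s gaps so each block has a clean pre-stimulus baseline).

## Problem sizes

The study runners default to the paradigm's stated sizes: 20 subjects ×
38 EEG channels × 3 intensities × 1000 clicks for the click study
(2280 averaged waveforms) and a 34-subject, 8-channel warble cohort.
The test suite exercises the same code paths at reduced click counts
where the asserted quantity (e.g. the 114-dataset and 2280-waveform
bookkeeping, which depend only on channels × intensities × subjects) is
invariant to them; the Monte-Carlo suites run at their stated sizes
(100 recovery seeds, 500 null tests/replicates).

## What passing tests do and do not show

The generators produce stationary Gaussian noise, perfectly periodic
systemic oscillations, a deterministic response template and no motion
artifacts, optode-coupling drifts or alpha/muscle EEG rhythms. Passing
recovery and error-control suites therefore demonstrates that the
*pipeline machinery* is correct and calibrated under its own model — not
that real recordings satisfy that model. Two limitations are worth
stating explicitly:

* The segmentwise two-sample t-test between stimulation and silence
  periods assumes exchangeable samples. Under slow shared systemic
  oscillations it is strongly anticonservative (rejection ≈ 0.5 at
  α = 0.05 on task-free simulations); its calibration is verified on the
  structure-free null, and its results on real-style data should be read
  as descriptive, not inferential. Component-based physiological
  denoising and short-channel regression are out of scope.
* PC1 recovers the injected kernel cleanly under measurement noise, but
  when shared Mayer-wave oscillations are strong it mixes them in
  (|r| with the kernel drops to ≈ 0.55 at the default systemic
  amplitudes). The GLM and ANOVA, whose group inference averages over
  random systemic phases, are the robust detectors in that regime.

EDF round-trips are exact only to the format's 16-bit quantization
(~1.5·10⁻⁵ of the per-channel range); SNIRF (HDF5, float64) round-trips
bit-exactly.
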