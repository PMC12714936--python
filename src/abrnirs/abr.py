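"""Click-ABR pipeline: filtering, epoching, averaging, wave scoring,
SNR, and EEG–fNIRS cross-modal correlation.

The processing chain mirrors standard brainstem evoked response
audiometry: band-pass the EEG to 100–3000 Hz, cut 12-ms epochs at each
click onset, average the ~1000 epochs per (channel, intensity),
normalize to the peak, and score Jewett waves I/III/V inside their
clinical latency windows.  The same scoring is mirrored on the fNIRS
total-hemoglobin trace, and temporal correspondence between the two
modalities is quantified by a lagged correlation within ±10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .stimuli import StimulusProtocol
from .synthetic import WAVE_WINDOWS_MS, Modality, TimeSeriesRecording

__all__ = [
    "EpochSet",
    "AveragedWaveform",
    "WavePeak",
    "WaveScore",
    "CrossModalResult",
    "bandpass",
    "epoch_clicks",
    "average_and_normalize",
    "detect_waves",
    "latency_deviation",
    "snr",
    "fnirs_click_trace",
    "crossmodal_correlation",
]


@dataclass
class EpochSet:
    """All epochs for one (channel, intensity) pair.

    ``baseline_mean``/``baseline_sd`` are per-sample statistics of the
    continuous filtered signal in the 0.5 s preceding the intensity
    block (a 12-ms epoch cannot contain its own 0.5-s baseline).
    """

    channel: str
    intensity: float
    epochs: np.ndarray  # trials x samples
    sample_rate: float
    epoch_ms: float
    baseline_mean: float
    baseline_sd: float
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class AveragedWaveform:
    """Per-channel, per-intensity epoch average.

    ``values`` is baseline-corrected and normalized to unit peak
    magnitude (unless the average was identically zero);
    ``peak_amplitude`` keeps the pre-normalization peak magnitude and
    ``baseline_sd`` the residual noise level expected in the average
    (continuous-baseline sd divided by sqrt(n_averaged)), so the SNR of
    the average can be formed after normalization.
    """

    channel: str
    intensity: float
    values: np.ndarray
    times_ms: np.ndarray
    n_averaged: int
    baseline_mean: float
    baseline_sd: float
    peak_amplitude: float
    normalized: bool = True

    @property
    def peak_value(self) -> float:
        """Peak on the original scale, including the baseline offset."""
        return self.baseline_mean + self.peak_amplitude


@dataclass(frozen=True)
class WavePeak:
    latency_ms: float
    amplitude: float


@dataclass
class WaveScore:
    """Detected ABR peaks plus derived quantities."""

    waves: dict[str, WavePeak | None]
    extra_peaks: list[WavePeak] = field(default_factory=list)
    latency_deviations: dict[str, float | None] = field(default_factory=dict)

    def interval(self, a: str, b: str) -> float | None:
        """Inter-peak interval b − a in ms, None unless both present."""
        wa, wb = self.waves.get(a), self.waves.get(b)
        if wa is None or wb is None:
            return None
        return wb.latency_ms - wa.latency_ms

    @property
    def intervals(self) -> dict[str, float | None]:
        return {
            "I-III": self.interval("I", "III"),
            "III-V": self.interval("III", "V"),
            "I-V": self.interval("I", "V"),
        }


@dataclass(frozen=True)
class CrossModalResult:
    peak_correlation: float
    lag_ms: float


def bandpass(
    rec: TimeSeriesRecording,
    low: float = 100.0,
    high: float = 3000.0,
    order: int = 4,
) -> TimeSeriesRecording:
    """Zero-phase Butterworth band-pass, applied forward and backward so
    group delay cannot bias latency scoring."""
    if rec.sample_rate <= 2 * high:
        raise ValueError("sample_rate must exceed twice the high cutoff")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return TimeSeriesRecording(
        rec.sample_rate, list(rec.channel_labels), data, list(rec.events), rec.modality
    )


def _block_starts(protocol: StimulusProtocol) -> dict[float, float]:
    """First click onset per intensity (blocks are contiguous per level)."""
    starts: dict[float, float] = {}
    for e in protocol.events:
        if e.kind == "click" and e.intensity not in starts:
            starts[e.intensity] = e.onset
    return starts


def epoch_clicks(
    rec: TimeSeriesRecording,
    protocol: StimulusProtocol,
    epoch_ms: float = 12.0,
    baseline_s: float = 0.5,
) -> dict[tuple[str, float], EpochSet]:
    """Cut one epoch per click (0 to +epoch_ms after onset) and group by
    intensity then channel.  Epochs that would run past the end of the
    recording are dropped and counted in ``n_dropped``."""
    fs = rec.sample_rate
    n_ep = int(round(epoch_ms * 1e-3 * fs))
    out: dict[tuple[str, float], EpochSet] = {}
    block_starts = _block_starts(protocol)
    for level, block_start in block_starts.items():
        onsets = np.array(
            [e.onset for e in protocol.events if e.kind == "click" and e.intensity == level]
        )
        starts = np.round(onsets * fs).astype(int)
        keep = starts + n_ep <= rec.n_samples
        n_dropped = int((~keep).sum())
        idx = starts[keep, None] + np.arange(n_ep)[None, :]

        b_hi = int(round(block_start * fs))
        b_lo = max(0, b_hi - int(round(baseline_s * fs)))
        for ch, label in enumerate(rec.channel_labels):
            baseline = rec.data[ch, b_lo:b_hi]
            out[(label, level)] = EpochSet(
                channel=label,
                intensity=level,
                epochs=rec.data[ch][idx] if keep.any() else np.empty((0, n_ep)),
                sample_rate=fs,
                epoch_ms=epoch_ms,
                baseline_mean=float(baseline.mean()) if baseline.size else 0.0,
                baseline_sd=float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0,
                n_dropped=n_dropped,
            )
    return out


def average_and_normalize(es: EpochSet) -> AveragedWaveform:
    """Average epochs, subtract the pre-block baseline mean, and
    normalize to unit peak magnitude.

    The stored ``baseline_sd`` is scaled by 1/sqrt(n) to estimate the
    residual noise of the average itself.  An identically zero average
    skips normalization and clears the ``normalized`` flag.
    """
    if es.n_trials < 1:
        raise ValueError("cannot average an empty epoch set")
    avg = es.epochs.mean(axis=0) - es.baseline_mean
    peak = float(np.abs(avg).max())
    normalized = peak > 0
    values = avg / peak if normalized else avg
    times_ms = np.arange(avg.size) / es.sample_rate * 1e3
    return AveragedWaveform(
        channel=es.channel,
        intensity=es.intensity,
        values=values,
        times_ms=times_ms,
        n_averaged=es.n_trials,
        baseline_mean=es.baseline_mean,
        baseline_sd=es.baseline_sd / np.sqrt(es.n_trials),
        peak_amplitude=peak,
        normalized=normalized,
    )


def detect_waves(
    wf: AveragedWaveform,
    windows: dict[str, tuple[float, float]] = WAVE_WINDOWS_MS,
    min_height: float = 0.08,
    min_distance_ms: float = 2.0,
) -> WaveScore:
    """Score Jewett waves on a normalized waveform.

    Local maxima meeting the height and (global) distance criteria are
    assigned to their latency windows; the highest qualifying peak per
    window wins, ties going to the earlier latency.  Qualifying peaks
    outside every window are reported as ``extra_peaks``; absence of a
    wave is a valid result, not an error.
    """
    dt_ms = wf.times_ms[1] - wf.times_ms[0] if wf.times_ms.size > 1 else 1.0
    distance = max(1, int(round(min_distance_ms / dt_ms)))
    peaks, props = sps.find_peaks(wf.values, height=min_height, distance=distance)
    candidates = [WavePeak(float(wf.times_ms[i]), float(wf.values[i])) for i in peaks]

    waves: dict[str, WavePeak | None] = {}
    assigned: set[WavePeak] = set()
    for name, (lo, hi) in windows.items():
        in_win = [p for p in candidates if lo <= p.latency_ms <= hi and p not in assigned]
        if in_win:
            best = max(in_win, key=lambda p: (p.amplitude, -p.latency_ms))
            waves[name] = best
            assigned.add(best)
        else:
            waves[name] = None
    extra = [p for p in candidates if p not in assigned]
    return WaveScore(waves=waves, extra_peaks=extra)


def latency_deviation(
    score: WaveScore, normative: dict[str, float]
) -> dict[str, float | None]:
    """Signed deviation (measured − normative) per wave, in ms; ``None``
    marks waves that were not detected.  The result is also stored on
    the score."""
    out: dict[str, float | None] = {}
    for name, norm in normative.items():
        peak = score.waves.get(name)
        out[name] = None if peak is None else peak.latency_ms - norm
    score.latency_deviations = out
    return out


def snr(wf: AveragedWaveform) -> float:
    """Signal-to-noise ratio of an averaged waveform: peak amplitude
    relative to the baseline mean, divided by the baseline-period
    standard deviation."""
    if wf.baseline_sd == 0:
        raise ValueError("baseline standard deviation is zero")
    return (wf.peak_value - wf.baseline_mean) / wf.baseline_sd


def fnirs_click_trace(
    chromo_rec: TimeSeriesRecording,
    protocol: StimulusProtocol,
    epoch_ms: float = 12.0,
    baseline_s: float = 2.0,
    target_rate: float = 16_000.0,
) -> dict[tuple[str, float], AveragedWaveform]:
    """Mirror the ABR epoch-average on the fNIRS total-hemoglobin trace.

    Δ[HbT] (= Δ[HbO] + Δ[HbR]) is interpolated onto the EEG epoch
    timeline, epoched at the click onsets, averaged per intensity, and
    baseline-corrected with the mean over the first ``baseline_s``
    seconds of the pre-stimulus (pre-block) period.
    """
    if chromo_rec.modality is not Modality.FNIRS_CHROMOPHORE:
        raise ValueError("fnirs_click_trace needs a chromophore recording")
    hbo, hbr, hbt, sites = chromo_rec.chromophores()
    times = chromo_rec.times
    n_ep = int(round(epoch_ms * 1e-3 * target_rate))
    rel_t = np.arange(n_ep) / target_rate

    out: dict[tuple[str, float], AveragedWaveform] = {}
    for level, block_start in _block_starts(protocol).items():
        onsets = np.array(
            [e.onset for e in protocol.events if e.kind == "click" and e.intensity == level]
        )
        onsets = onsets[onsets + epoch_ms * 1e-3 <= chromo_rec.duration]
        sample_times = (onsets[:, None] + rel_t[None, :]).ravel()
        b_lo = max(0.0, block_start - baseline_s)
        b_mask = (times >= b_lo) & (times < block_start)
        for s_idx, site in enumerate(sites):
            trace = hbt[s_idx]
            epochs = np.interp(sample_times, times, trace).reshape(len(onsets), n_ep)
            baseline = trace[b_mask]
            base_mean = float(baseline.mean()) if baseline.size else 0.0
            base_sd = float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0
            avg = epochs.mean(axis=0) - base_mean
            peak = float(np.abs(avg).max())
            normalized = peak > 0
            out[(site, level)] = AveragedWaveform(
                channel=site,
                intensity=level,
                values=avg / peak if normalized else avg,
                times_ms=rel_t * 1e3,
                n_averaged=len(onsets),
                baseline_mean=base_mean,
                baseline_sd=base_sd / np.sqrt(max(len(onsets), 1)),
                peak_amplitude=peak,
                normalized=normalized,
            )
    return out


def crossmodal_correlation(
    eeg_wf: AveragedWaveform,
    fnirs_wf: AveragedWaveform,
    max_lag_ms: float = 10.0,
    grid_hz: float = 256.0,
    min_overlap: int = 3,
) -> CrossModalResult:
    """Peak lagged correlation between EEG and fNIRS waveforms.

    Both waveforms are linearly interpolated onto a common ``grid_hz``
    grid (256 Hz gives the 3.906-ms lag quantization of the reported
    lags), correlated at every integer-step lag within ±``max_lag_ms``,
    and the lag with the largest \\|r\\| is returned with its signed r.
    Ties prefer the smaller \\|lag\\|.
    """
    t0 = max(eeg_wf.times_ms[0], fnirs_wf.times_ms[0])
    t1 = min(eeg_wf.times_ms[-1], fnirs_wf.times_ms[-1])
    if t1 <= t0:
        raise ValueError("waveform time ranges do not overlap")
    step_ms = 1e3 / grid_hz
    grid = np.arange(t0, t1 + 1e-9, step_ms)
    if grid.size < min_overlap:
        raise ValueError("waveforms too short for the correlation grid")
    a = np.interp(grid, eeg_wf.times_ms, eeg_wf.values)
    b = np.interp(grid, fnirs_wf.times_ms, fnirs_wf.values)

    max_steps = int(max_lag_ms / step_ms)
    best = CrossModalResult(0.0, 0.0)
    best_key = (-np.inf, np.inf)
    for k in range(-max_steps, max_steps + 1):
        if k >= 0:
            x, y = a[k:], b[: b.size - k]
        else:
            x, y = a[: a.size + k], b[-k:]
        if x.size < min_overlap:
            continue
        sx, sy = x.std(), y.std()
        r = 0.0 if sx == 0 or sy == 0 else float(
            ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
        )
        key = (abs(r), -abs(k))
        if key > best_key:
            best_key = key
            best = CrossModalResult(r, k * step_ms)
    return best
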