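"""Seeded generators for synthetic EEG (click ABR) and fNIRS recordings.

The generators produce recordings with a fully known ground truth so that
every downstream stage — filtering, epoching, peak scoring, GLM, ANOVA —
has a recoverable target:

* EEG: each click evokes a stereotyped brainstem template built from
  Gaussian bumps at the Jewett wave I/III/V latencies for that stimulus
  intensity; overlapping responses at the 81.9 Hz repetition rate sum
  linearly, and white sensor noise is added on top.
* fNIRS: each warble block evokes a slow negative-going intensity change
  (a gamma-shaped kernel troughing ~12 s after onset), superimposed on
  shared systemic oscillations (cardiac ~1.1 Hz, respiratory ~0.3 Hz,
  vasomotor ~0.1 Hz), a linear drift and white noise.  A paired
  chromophore recording carries Δ[HbO] and Δ[HbR] whose sum is the total
  hemoglobin change Δ[HbT] implied by the intensity response.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .stimuli import StimulusEvent, StimulusProtocol

__all__ = [
    "Modality",
    "TimeSeriesRecording",
    "AbrTruth",
    "HemoTruth",
    "WAVE_WINDOWS_MS",
    "DEFAULT_FNIRS_CHANNELS",
    "gamma_response_kernel",
    "simulate_abr",
    "simulate_fnirs",
    "simulate_breath_hold",
    "make_null_cohort",
]

#: ABR scoring windows in ms (wave -> (low, high)).
WAVE_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "I": (1.6, 3.5),
    "III": (3.6, 5.5),
    "V": (5.6, 8.0),
}

DEFAULT_FNIRS_CHANNELS: tuple[str, ...] = (
    "S1-D1", "S1-D2", "S2-D1", "S2-D2",
    "S3-D3", "S3-D4", "S4-D3", "S4-D4",
)


class Modality(str, Enum):
    EEG = "eeg"
    FNIRS_RAW = "fnirs_raw"
    FNIRS_CHROMOPHORE = "fnirs_chromophore"


@dataclass
class TimeSeriesRecording:
    """Uniformly sampled multichannel recording plus its event list.

    ``data`` is channels x samples in physical units: µV for EEG,
    arbitrary intensity for raw fNIRS, µM for chromophore recordings
    (labels carry an ``" HbO"`` / ``" HbR"`` suffix).
    """

    sample_rate: float
    channel_labels: list[str]
    data: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)
    modality: Modality = Modality.EEG

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel_labels")
        span = self.n_samples / self.sample_rate
        for e in self.events:
            if e.onset > span:
                raise ValueError(f"event at {e.onset}s outside recording span {span}s")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def chromophores(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Split a chromophore recording into (ΔHbO, ΔHbR, ΔHbT, sites).

        ΔHbT is computed as the elementwise sum ΔHbO + ΔHbR.
        """
        if self.modality is not Modality.FNIRS_CHROMOPHORE:
            raise ValueError("not a chromophore recording")
        sites = [lb[: -len(" HbO")] for lb in self.channel_labels if lb.endswith(" HbO")]
        if not sites:
            raise ValueError("recording lacks HbO channels")
        try:
            hbo = np.stack([self.data[self.channel_labels.index(s + " HbO")] for s in sites])
            hbr = np.stack([self.data[self.channel_labels.index(s + " HbR")] for s in sites])
        except ValueError as err:
            raise ValueError("recording lacks matching HbR channels") from err
        return hbo, hbr, hbo + hbr, sites


# ---------------------------------------------------------------------------
# EEG / ABR
# ---------------------------------------------------------------------------

def _default_abr_tables() -> tuple[dict, dict]:
    # latency grows and amplitude shrinks as the click gets quieter;
    # values sit inside the standard scoring windows
    latencies = {
        90.0: (1.9, 4.1, 6.1),
        70.0: (2.5, 4.7, 6.7),
        50.0: (3.1, 5.3, 7.5),
    }
    amplitudes = {  # µV; wave V ~0.5 µV at 90 dB is a typical scalp ABR
        90.0: (0.15, 0.30, 0.50),
        70.0: (0.09, 0.18, 0.30),
        50.0: (0.04, 0.08, 0.125),
    }
    return latencies, amplitudes


@dataclass
class AbrTruth:
    """Ground truth for the ABR simulator.

    ``latencies_ms``/``amplitudes_uv`` map stimulus intensity (dB SPL) to
    the (I, III, V) wave latencies in ms / peak amplitudes in µV.
    ``bump_width_ms`` is the full width at half maximum of each Gaussian
    bump.  ``noise_sd`` is the white-noise standard deviation in µV; the
    default puts the per-click wave-V SNR near 0.1 so that only
    1000-trial averages reveal the response, as in real ABR recordings.
    """

    latencies_ms: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: _default_abr_tables()[0]
    )
    amplitudes_uv: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: _default_abr_tables()[1]
    )
    bump_width_ms: float = 0.4
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for level, lats in self.latencies_ms.items():
            if list(lats) != sorted(lats):
                raise ValueError(f"latencies at {level} dB not ordered I<=III<=V")
            for name, lat in zip(("I", "III", "V"), lats):
                lo, hi = WAVE_WINDOWS_MS[name]
                if not lo <= lat <= hi:
                    raise ValueError(
                        f"wave {name} latency {lat} ms outside window [{lo}, {hi}]"
                    )
        for level, amps in self.amplitudes_uv.items():
            if any(a < 0 for a in amps):
                raise ValueError(f"negative amplitude at {level} dB")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def template(self, intensity: float, sample_rate: float) -> np.ndarray:
        """The per-click response template at ``intensity``, sampled at
        ``sample_rate`` from t=0 to just past the last bump."""
        lats = np.array(self.latencies_ms[intensity]) * 1e-3
        amps = np.array(self.amplitudes_uv[intensity])
        sigma = self.bump_width_ms * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        t_max = lats.max() + 5 * sigma
        t = np.arange(0.0, t_max, 1.0 / sample_rate)
        out = np.zeros_like(t)
        for lat, amp in zip(lats, amps):
            out += amp * np.exp(-0.5 * ((t - lat) / sigma) ** 2)
        return out


def simulate_abr(
    protocol: StimulusProtocol,
    truth: AbrTruth,
    n_channels: int = 1,
    sample_rate: float = 16_000.0,
    channel_labels: list[str] | None = None,
) -> TimeSeriesRecording:
    """Synthesize an EEG recording of a click protocol.

    Each click adds the intensity-specific template at its onset;
    responses to clicks closer together than the template length overlap
    and sum linearly.  Independent white noise of sd ``truth.noise_sd``
    is added per channel.  Deterministic given ``truth.seed``.
    """
    if sample_rate < 10_000:
        raise ValueError("sample_rate must be >= 10 kHz to resolve 0.1-ms clicks")
    clicks = [e for e in protocol.events if e.kind == "click"]
    missing = {e.intensity for e in clicks} - set(truth.latencies_ms)
    if missing:
        raise ValueError(f"protocol intensities {sorted(missing)} absent from truth")

    tail = 0.012  # room for the response to the last click
    n = int(np.ceil((protocol.total_duration + tail) * sample_rate)) or 1
    clean = np.zeros(n)
    for level in {e.intensity for e in clicks}:
        impulses = np.zeros(n)
        idx = np.round(
            [e.onset * sample_rate for e in clicks if e.intensity == level]
        ).astype(int)
        impulses[idx[idx < n]] = 1.0
        tmpl = truth.template(level, sample_rate)
        from scipy.signal import fftconvolve

        clean += fftconvolve(impulses, tmpl)[:n]

    rng = np.random.default_rng(truth.seed)
    data = clean + rng.normal(0.0, truth.noise_sd, size=(n_channels, n))
    labels = channel_labels or [f"EEG{i + 1:03d}" for i in range(n_channels)]
    return TimeSeriesRecording(
        sample_rate, labels, data, list(protocol.events), Modality.EEG
    )


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------

def _default_betas() -> np.ndarray:
    # fractional intensity drops of 1-2%, heterogeneous across channels
    return np.array(
        [-0.0142, -0.010, -0.0227, -0.008, -0.012, -0.0173, -0.015, -0.018]
    )


@dataclass
class HemoTruth:
    """Ground truth for the fNIRS simulator.

    ``channel_betas`` are fractional intensity changes per channel
    (negative = the stimulus darkens the channel, the physiological
    direction for an HbT increase).  The response kernel is a gamma
    density troughing ``trough_latency`` s after onset and returning to
    baseline by roughly ``response_duration`` s.  Systemic amplitudes
    are fractional intensity oscillations shared by all channels.
    """

    channel_betas: np.ndarray = field(default_factory=_default_betas)
    trough_latency: float = 12.0
    response_duration: float = 30.0
    cardiac_amp: float = 0.005
    cardiac_freq: float = 1.1
    respiratory_amp: float = 0.005
    respiratory_freq: float = 0.3
    vasomotor_amp: float = 0.008
    vasomotor_freq: float = 0.1
    drift_slope: float = 1e-4
    noise_sd: float = 0.005
    baseline: float = 1.0
    hbt_scale: float = 50.0  # µM of ΔHbT per unit fractional intensity drop
    hbo_fraction: float = 1.4  # ΔHbO = 1.4 ΔHbT, hence ΔHbR = -0.4 ΔHbT
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_betas = np.asarray(self.channel_betas, dtype=float)
        if not np.all(np.isfinite(self.channel_betas)):
            raise ValueError("channel_betas must be finite")
        if not 0 < self.trough_latency < self.response_duration:
            raise ValueError("need 0 < trough_latency < response_duration")

    def with_betas(self, betas: np.ndarray) -> "HemoTruth":
        from dataclasses import replace

        return replace(self, channel_betas=np.asarray(betas, dtype=float))


def gamma_response_kernel(
    trough_latency: float,
    response_duration: float,
    sample_rate: float,
) -> np.ndarray:
    """Unit-peak gamma-density kernel with its mode at ``trough_latency``.

    The gamma shape/scale are solved so the mode is ``trough_latency``
    and the density has effectively returned to zero (mode + 3 sd) at
    ``response_duration``.  Returned positive with peak 1; multiply by a
    negative beta for the intensity-decrease response.
    """
    m = float(trough_latency)
    s = (float(response_duration) - m) / 3.0
    if s <= 0:
        raise ValueError("response_duration must exceed trough_latency")
    # mode (k-1)θ = m and sd √k θ = s  ->  s²k² - (2s² + m²)k + s² = 0
    b = 2 * s**2 + m**2
    k = (b + np.sqrt(b**2 - 4 * s**4)) / (2 * s**2)
    theta = m / (k - 1.0)
    t = np.arange(0.0, m + 5 * s, 1.0 / sample_rate)
    pdf = stats.gamma.pdf(t, k, scale=theta)
    return pdf / stats.gamma.pdf(m, k, scale=theta)


def _task_response(
    protocol: StimulusProtocol, n: int, sample_rate: float, truth: HemoTruth
) -> np.ndarray:
    """Sum of response kernels at each warble onset, unit peak per event."""
    r = np.zeros(n)
    kernel = gamma_response_kernel(
        truth.trough_latency, truth.response_duration, sample_rate
    )
    for e in protocol.events:
        if e.kind == "silence":
            continue
        i0 = int(round(e.onset * sample_rate))
        seg = kernel[: max(0, n - i0)]
        r[i0 : i0 + len(seg)] += seg
    return r


def _systemic(times: np.ndarray, truth: HemoTruth, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(times)
    for amp, freq in (
        (truth.cardiac_amp, truth.cardiac_freq),
        (truth.respiratory_amp, truth.respiratory_freq),
        (truth.vasomotor_amp, truth.vasomotor_freq),
    ):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += amp * np.sin(2.0 * np.pi * freq * times + phase)
    return out


def simulate_fnirs(
    protocol: StimulusProtocol,
    truth: HemoTruth,
    channel_labels: list[str] | None = None,
    sample_rate: float = 10.0,
) -> tuple[TimeSeriesRecording, TimeSeriesRecording]:
    """Synthesize a raw-intensity fNIRS recording and its paired
    chromophore recording for a warble block design.

    Raw intensity per channel is
    ``baseline * (1 + beta_ch * r(t) + systemic(t) + drift * t + noise)``
    where ``r(t)`` is the unit-peak task response.  The chromophore
    recording carries ΔHbO and ΔHbR per channel with
    ΔHbO + ΔHbR = ΔHbT = -hbt_scale * (beta_ch * r(t) + systemic(t)),
    i.e. an intensity decrease maps to an HbT increase.
    """
    if sample_rate < 2:
        raise ValueError("sample_rate must be >= 2 Hz")
    labels = list(channel_labels) if channel_labels is not None else list(
        DEFAULT_FNIRS_CHANNELS
    )
    if not labels:
        raise ValueError("channel list must not be empty")
    betas = np.broadcast_to(truth.channel_betas, (len(labels),)) if (
        truth.channel_betas.size == 1
    ) else truth.channel_betas
    if betas.shape[0] != len(labels):
        raise ValueError("channel_betas length must match channel_labels")

    n = int(round(protocol.total_duration * sample_rate))
    times = np.arange(n) / sample_rate
    r = _task_response(protocol, n, sample_rate, truth)

    rng = np.random.default_rng(truth.seed)
    systemic = _systemic(times, truth, rng)
    drift = truth.drift_slope * times

    frac = betas[:, None] * r[None, :] + systemic[None, :] + drift[None, :]
    noise = rng.normal(0.0, truth.noise_sd, size=(len(labels), n)) if truth.noise_sd else 0.0
    raw = truth.baseline * (1.0 + frac + noise)
    raw_rec = TimeSeriesRecording(
        sample_rate, labels, raw, list(protocol.events), Modality.FNIRS_RAW
    )

    hbt = -truth.hbt_scale * (betas[:, None] * r[None, :] + systemic[None, :])
    chromo_noise = truth.hbt_scale * truth.noise_sd
    noise_o = rng.normal(0.0, chromo_noise, size=hbt.shape) if truth.noise_sd else 0.0
    noise_r = rng.normal(0.0, chromo_noise, size=hbt.shape) if truth.noise_sd else 0.0
    hbo = truth.hbo_fraction * hbt + noise_o
    hbr = (1.0 - truth.hbo_fraction) * hbt + noise_r
    chromo_rec = TimeSeriesRecording(
        sample_rate,
        [f"{lb} HbO" for lb in labels] + [f"{lb} HbR" for lb in labels],
        np.vstack([hbo, hbr]),
        list(protocol.events),
        Modality.FNIRS_CHROMOPHORE,
    )
    return raw_rec, chromo_rec


def simulate_breath_hold(
    truth: HemoTruth,
    hold_onsets: list[float],
    protocol: StimulusProtocol | None = None,
    channel_labels: list[str] | None = None,
    sample_rate: float = 10.0,
    hold_amplitude: float = -0.03,
    hold_duration: float = 15.0,
) -> tuple[TimeSeriesRecording, TimeSeriesRecording]:
    """A recording with a global systemic excursion added for each breath
    hold: the same slow Gaussian-shaped fractional intensity change on
    every channel, mimicking a blood-pressure/CO2 event that spatial
    analyses should classify as non-specific.

    With no holds (or zero amplitude) the output equals
    :func:`simulate_fnirs` for the same truth and protocol.
    """
    if protocol is None:
        from .stimuli import build_warble_protocol

        protocol = build_warble_protocol()
    onsets = sorted(hold_onsets)
    for a, b in zip(onsets, onsets[1:]):
        if b < a + hold_duration:
            raise ValueError("breath holds overlap")
    if any(o < 0 or o + hold_duration > protocol.total_duration for o in onsets):
        raise ValueError("breath hold outside recording span")

    raw_rec, chromo_rec = simulate_fnirs(protocol, truth, channel_labels, sample_rate)
    if not onsets or hold_amplitude == 0.0:
        return raw_rec, chromo_rec

    times = np.arange(raw_rec.n_samples) / sample_rate
    excursion = np.zeros_like(times)
    sigma = hold_duration / 4.0
    for onset in onsets:
        center = onset + hold_duration / 2.0
        excursion += hold_amplitude * np.exp(-0.5 * ((times - center) / sigma) ** 2)

    raw_rec.data = raw_rec.data + truth.baseline * excursion[None, :]
    n_sites = raw_rec.n_channels
    hbt_exc = -truth.hbt_scale * excursion
    chromo_rec.data[:n_sites] += truth.hbo_fraction * hbt_exc
    chromo_rec.data[n_sites:] += (1.0 - truth.hbo_fraction) * hbt_exc
    return raw_rec, chromo_rec


def make_null_cohort(
    n_subjects: int,
    seed: int,
    protocol: StimulusProtocol | None = None,
    channel_labels: list[str] | None = None,
    sample_rate: float = 10.0,
    truth: HemoTruth | None = None,
) -> list[tuple[TimeSeriesRecording, TimeSeriesRecording]]:
    """Cohort of task-free recordings: realistic noise/systemic/drift but
    every channel beta set to zero, for type-I-error measurement."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if protocol is None:
        from .stimuli import build_warble_protocol

        protocol = build_warble_protocol()
    base = truth if truth is not None else HemoTruth()
    labels = list(channel_labels) if channel_labels is not None else list(
        DEFAULT_FNIRS_CHANNELS
    )
    cohort = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    for s in child_seeds:
        from dataclasses import replace

        t = replace(base, channel_betas=np.zeros(len(labels)), seed=int(s))
        cohort.append(simulate_fnirs(protocol, t, labels, sample_rate))
    return cohort
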