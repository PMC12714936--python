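"""Stimulation protocols and sound-level calibration.

Two auditory paradigms are supported:

* a click train for auditory brainstem response (ABR) recording —
  0.1 ms broadband clicks delivered at a fixed repetition rate, in one
  contiguous block per stimulus intensity;
* a 92-s block design built around a 2-s "warble" stimulus (a rapid
  alternating-polarity click sequence) presented at 50/70/90 dB SPL with
  silent rest periods in between.

Sound levels are mapped to headphone drive voltages through a single
calibration point via the standard decibel relation
``dB1 - dB2 = 20 * log10(V1 / V2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "StimulusEvent",
    "StimulusProtocol",
    "db_to_voltage",
    "voltage_to_db",
    "build_click_protocol",
    "build_warble_protocol",
    "synth_warble_samples",
    "write_protocol",
    "read_protocol",
]

EVENT_KINDS = ("click", "warble", "silence")


@dataclass(frozen=True)
class CalibrationPoint:
    """A known (sound level, drive voltage) pair for one transducer.

    Parameters
    ----------
    reference_db : float
        Sound level in dB SPL produced by the reference voltage.
    reference_voltage : float
        Drive voltage in mV that produces ``reference_db``.
    """

    reference_db: float
    reference_voltage: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.reference_db):
            raise ValueError("reference_db must be finite")
        if not (self.reference_voltage > 0 and math.isfinite(self.reference_voltage)):
            raise ValueError("reference_voltage must be positive and finite")


@dataclass(frozen=True)
class StimulusEvent:
    """One timed stimulus: onset/duration in seconds, intensity in dB SPL."""

    onset: float
    duration: float
    intensity: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.kind in ("click", "warble") and not self.duration > 0:
            raise ValueError("click/warble events need duration > 0")


@dataclass
class StimulusProtocol:
    """An ordered, non-overlapping event list with a total duration."""

    events: list[StimulusEvent] = field(default_factory=list)
    total_duration: float = 0.0
    repetition_rate: float | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        last_end = max((e.onset + e.duration for e in self.events), default=0.0)
        if self.total_duration + 1e-12 < last_end:
            raise ValueError("total_duration shorter than last event end")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, kind: str | None = None) -> np.ndarray:
        """Event onsets in seconds, optionally restricted to one kind."""
        return np.array(
            [e.onset for e in self.events if kind is None or e.kind == kind]
        )

    def intensities(self) -> list[float]:
        """Distinct stimulus intensities in order of first appearance."""
        seen: list[float] = []
        for e in self.events:
            if e.kind != "silence" and e.intensity not in seen:
                seen.append(e.intensity)
        return seen


def db_to_voltage(target_db: float, calib: CalibrationPoint) -> float:
    """Drive voltage (mV) that produces ``target_db`` dB SPL.

    Inverts ``dB1 - dB2 = 20 log10(V1/V2)`` for V2 given the calibration
    reference (dB1, V1): ``V2 = V1 * 10**((target_db - dB1) / 20)``.
    """
    if not math.isfinite(target_db):
        raise ValueError("target_db must be finite")
    return calib.reference_voltage * 10.0 ** ((target_db - calib.reference_db) / 20.0)


def voltage_to_db(voltage: float, calib: CalibrationPoint) -> float:
    """Sound level (dB SPL) produced by ``voltage`` mV; inverse of db_to_voltage."""
    if not (voltage > 0 and math.isfinite(voltage)):
        raise ValueError("voltage must be positive and finite")
    return calib.reference_db - 20.0 * math.log10(calib.reference_voltage / voltage)


def build_click_protocol(
    rate: float,
    clicks_per_intensity: int,
    intensities: list[float],
    click_duration: float = 1e-4,
    start: float = 0.0,
    inter_block_gap: float = 0.0,
) -> StimulusProtocol:
    """Click train: one contiguous block of clicks per intensity.

    Clicks within a block are spaced at the inter-onset interval 1/rate.
    ``start`` shifts the first block (silent lead-in) and
    ``inter_block_gap`` inserts silence between consecutive blocks; both
    default to 0 so blocks are concatenated back to back.
    """
    if not rate > 0:
        raise ValueError("rate must be > 0")
    if clicks_per_intensity < 0:
        raise ValueError("clicks_per_intensity must be >= 0")
    isi = 1.0 / rate
    events: list[StimulusEvent] = []
    t = start
    for level in intensities:
        for _ in range(clicks_per_intensity):
            events.append(StimulusEvent(t, click_duration, level, "click"))
            t += isi
        t += inter_block_gap
    total = events[-1].onset + isi if events else 0.0
    return StimulusProtocol(events, total_duration=total, repetition_rate=rate)


#: (duration s, intensity dB SPL or None for silence) segments of the
#: 92-s warble block design.
WARBLE_SEGMENTS: tuple[tuple[float, float | None], ...] = (
    (30.0, None),
    (2.0, 50.0),
    (13.0, None),
    (2.0, 70.0),
    (13.0, None),
    (2.0, 90.0),
    (30.0, None),
)


def build_warble_protocol() -> StimulusProtocol:
    """The 92-s block design: 30 s silence, then 2-s warbles at 50/70/90
    dB SPL separated by 13 s of silence, then 30 s of silence."""
    events: list[StimulusEvent] = []
    t = 0.0
    for duration, level in WARBLE_SEGMENTS:
        if level is not None:
            events.append(StimulusEvent(t, duration, level, "warble"))
        t += duration
    return StimulusProtocol(events, total_duration=t, repetition_rate=None)


def synth_warble_samples(
    duration: float, sample_rate: float, pulse_rate: float = 100.0
) -> np.ndarray:
    """Audio samples of the warble stimulus: an alternating-polarity pulse
    train (zero mean by construction), ``pulse_rate`` pulses per second.

    The alternating polarity drives the headphone diaphragm in both
    directions; the exact pulse rate is a free design parameter.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if sample_rate < 2 * pulse_rate:
        raise ValueError("sample_rate too low to represent the pulse train")
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    n_pulses = int(round(pulse_rate * duration))
    for k in range(n_pulses):
        idx = int(round(k / pulse_rate * sample_rate))
        if idx < n:
            out[idx] = 1.0 if k % 2 == 0 else -1.0
    # enforce an exactly zero mean when the pulse count is odd
    if n_pulses % 2 == 1 and n_pulses > 0:
        out -= out.sum() / n
    return out


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    """Serialize a protocol as a tab-separated event table.

    Columns: onset_s, duration_s, intensity_db, kind (header required).
    """
    df = pd.DataFrame(
        {
            "onset_s": [e.onset for e in protocol.events],
            "duration_s": [e.duration for e in protocol.events],
            "intensity_db": [e.intensity for e in protocol.events],
            "kind": [e.kind for e in protocol.events],
        }
    )
    df.attrs["total_duration"] = protocol.total_duration
    with open(path, "w") as fh:
        fh.write(f"# total_duration_s={protocol.total_duration!r}")
        if protocol.repetition_rate is not None:
            fh.write(f"\trepetition_rate_hz={protocol.repetition_rate!r}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)


def read_protocol(path: str | Path) -> StimulusProtocol:
    """Read a protocol from the tab-separated dialect of :func:`write_protocol`."""
    with open(path) as fh:
        first = fh.readline()
        meta: dict[str, float] = {}
        if first.startswith("#"):
            for token in first[1:].strip().split("\t"):
                key, _, value = token.partition("=")
                meta[key.strip()] = float(value)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    events = [
        StimulusEvent(row.onset_s, row.duration_s, row.intensity_db, row.kind)
        for row in df.itertuples()
    ]
    last_end = max((e.onset + e.duration for e in events), default=0.0)
    total = meta.get("total_duration_s", last_end)
    rate = meta.get("repetition_rate_hz")
    return StimulusProtocol(events, total_duration=total, repetition_rate=rate)
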