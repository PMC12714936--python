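"""European Data Format (EDF+) reading and writing for EEG recordings.

The writer emits standard EDF+C: 16-bit samples with per-channel
physical scaling and an ``EDF Annotations`` signal carrying one
time-stamped annotation list (TAL) per stimulus event, encoded as
``kind@intensity`` (e.g. ``click@90``).  Because EDF stores whole data
records, the final record is zero-padded; the exact sample count is
stashed in each signal's 32-byte reserved header field (``NS=<n>``) so
this module's reader can trim the padding.  Files from other writers are
read on a best-effort basis (untrimmed).

EDF quantizes to 16 bits, so amplitudes round-trip to roughly 2^-16 of
the per-channel physical range, not to full float precision.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from ..stimuli import StimulusEvent
from ..synthetic import Modality, TimeSeriesRecording

__all__ = ["write_eeg", "read_eeg"]

_HDR = 256  # bytes, fixed header and per-signal header block size


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num8_at_least(value: float, width: int = 7) -> float:
    """Largest-precision representation of positive ``value`` that fits in
    ``width`` ASCII chars (7 leaves room for a leading minus sign in the
    8-char EDF numeric field) and is >= value, so scaling never clips."""
    for prec in range(width, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            if float(s) >= value:
                return float(s)
            bumped = f"{value * (1 + 10.0 ** -prec):.{prec}g}"
            if len(bumped) <= width and float(bumped) >= value:
                return float(bumped)
    raise ValueError(f"cannot encode {value} in an EDF numeric field")


def _annotation_payloads(events: list[StimulusEvent], n_records: int,
                         record_duration: float) -> list[bytes]:
    """One TAL byte string per record: the record's time-keeping TAL plus
    TALs for every event whose onset falls inside the record."""
    payloads = []
    per_record: list[list[StimulusEvent]] = [[] for _ in range(n_records)]
    for e in events:
        idx = min(int(e.onset / record_duration), n_records - 1)
        per_record[idx].append(e)
    for rec_idx in range(n_records):
        chunks = [f"+{rec_idx * record_duration:g}\x14\x14\x00".encode("ascii")]
        for e in per_record[rec_idx]:
            tal = f"+{e.onset:.6f}\x15{e.duration:.6f}\x14{e.kind}@{e.intensity:g}\x14\x00"
            chunks.append(tal.encode("ascii"))
        payloads.append(b"".join(chunks))
    return payloads


def write_eeg(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write an EEG recording as EDF+C with annotation-encoded events."""
    if rec.n_channels == 0:
        raise ValueError("recording has no channels")
    fs = rec.sample_rate
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9 * fs or spr < 1:
        raise ValueError("EDF writer requires an integer sample rate")
    record_duration = 1.0
    n_records = max(1, int(np.ceil(rec.n_samples / spr)))

    payloads = _annotation_payloads(list(rec.events), n_records, record_duration)
    ann_bytes = max(64, max(len(p) for p in payloads))
    ann_spr = (ann_bytes + 1) // 2  # 2 bytes per nominal sample

    nsig = rec.n_channels + 1
    header_bytes = _HDR + _HDR * nsig

    # per-channel symmetric physical range; 16-bit digital range
    absmax = np.array(
        [_num8_at_least(v) for v in np.maximum(np.abs(rec.data).max(axis=1), 1e-9)]
    )
    phys_min, phys_max = -absmax, absmax
    dig_min, dig_max = -32767, 32767

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field(f"{record_duration:g}", 8))
        fh.write(_field(str(nsig), 4))

        labels = list(rec.channel_labels) + ["EDF Annotations"]
        fh.write(b"".join(_field(lb, 16) for lb in labels))
        fh.write(b"".join(_field("", 80) for _ in labels))  # transducer
        fh.write(b"".join(_field("uV", 8) for _ in rec.channel_labels) + _field("", 8))
        for lo in list(phys_min) + [-1.0]:
            fh.write(_field(f"{lo:.8g}", 8))
        for hi in list(phys_max) + [1.0]:
            fh.write(_field(f"{hi:.8g}", 8))
        fh.write(b"".join(_field(str(dig_min), 8) for _ in labels))
        fh.write(b"".join(_field(str(dig_max), 8) for _ in labels))
        fh.write(b"".join(_field("", 80) for _ in labels))  # prefiltering
        fh.write(b"".join(_field(str(spr), 8) for _ in rec.channel_labels))
        fh.write(_field(str(ann_spr), 8))
        fh.write(b"".join(_field(f"NS={rec.n_samples}", 32) for _ in labels))

        # digital conversion
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        padded = np.zeros((rec.n_channels, n_records * spr))
        padded[:, : rec.n_samples] = rec.data
        digital = np.clip(
            np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min),
            dig_min,
            dig_max,
        ).astype("<i2")

        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            fh.write(payloads[r].ljust(2 * ann_spr, b"\x00"))


_TAL_RE = re.compile(
    rb"([+-]\d+(?:\.\d+)?)(?:\x15(\d+(?:\.\d+)?))?\x14([^\x14]*)\x14"
)


def _parse_events(ann_raw: bytes) -> list[StimulusEvent]:
    events = []
    for m in _TAL_RE.finditer(ann_raw):
        text = m.group(3).decode("ascii", errors="replace")
        if not text:
            continue  # record time-keeping TAL
        kind, _, level = text.partition("@")
        if kind not in ("click", "warble", "silence"):
            continue
        onset = float(m.group(1))
        duration = float(m.group(2)) if m.group(2) else 0.0
        events.append(StimulusEvent(onset, duration, float(level or 0.0), kind))
    events.sort(key=lambda e: e.onset)
    return events


def read_eeg(path: str | Path) -> TimeSeriesRecording:
    """Read an EDF/EDF+ file into a :class:`TimeSeriesRecording` (µV).

    Stimulus events are reconstructed from ``kind@intensity``
    annotations; a file without annotations yields an empty event list
    with a warning.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise ValueError("malformed EDF: truncated header")
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        nsig = int(head[252:256])
        sig = fh.read(_HDR * nsig)
        if len(sig) < _HDR * nsig:
            raise ValueError("malformed EDF: truncated signal headers")

        def col(offset: int, width: int) -> list[str]:
            base = offset * nsig
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(nsig)
            ]

        # cumulative byte offsets of the field-major signal header blocks:
        # label 0, transducer 16, physdim 96, physmin 104, physmax 112,
        # digmin 120, digmax 128, prefilter 136, samples/record 216,
        # reserved 224
        labels = col(0, 16)
        phys_min = col(104, 8)
        phys_max = col(112, 8)
        dig_min = col(120, 8)
        dig_max = col(128, 8)
        spr = [int(x) for x in col(216, 8)]
        reserved = col(224, 32)

        is_ann = [lb == "EDF Annotations" for lb in labels]
        data_idx = [i for i in range(nsig) if not is_ann[i]]
        if not data_idx:
            raise ValueError("EDF file has no data channels")
        # channels must share one sampling rate; drop any oddballs
        rates = [spr[i] for i in data_idx]
        modal = max(set(rates), key=rates.count)
        skipped = [labels[i] for i in data_idx if spr[i] != modal]
        if skipped:
            warnings.warn(f"skipping channels with non-modal sample rate: {skipped}")
        data_idx = [i for i in data_idx if spr[i] == modal]

        total_per_record = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
        if raw.size < n_records * total_per_record:
            raise ValueError("malformed EDF: truncated data")
        raw = raw[: n_records * total_per_record].reshape(n_records, total_per_record)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    channels = []
    for i in data_idx:
        dig = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        pmin, pmax = float(phys_min[i]), float(phys_max[i])
        dmin, dmax = float(dig_min[i]), float(dig_max[i])
        channels.append(pmin + (dig - dmin) * (pmax - pmin) / (dmax - dmin))
    data = np.vstack(channels)

    m = re.match(r"NS=(\d+)", reserved[data_idx[0]])
    if m:
        data = data[:, : int(m.group(1))]

    events: list[StimulusEvent] = []
    ann_idx = [i for i in range(nsig) if is_ann[i]]
    if ann_idx:
        i = ann_idx[0]
        ann_raw = raw[:, offsets[i] : offsets[i + 1]].astype("<i2").tobytes()
        events = _parse_events(ann_raw)
    else:
        warnings.warn("EDF file has no annotations; event list is empty")

    fs = spr[data_idx[0]] / record_duration
    return TimeSeriesRecording(
        fs, [labels[i] for i in data_idx], data, events, Modality.EEG
    )
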