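"""SNIRF (Shared Near Infrared Spectroscopy Format) reading and writing.

Implements the subset of the SNIRF 1.0 HDF5 layout the pipelines need:
one ``/nirs`` group with a single data block (``dataTimeSeries`` +
``time`` + ``measurementList``), a probe group, and one stim group per
distinct (kind, intensity) stimulus.  Raw recordings use dataType 1
(continuous-wave amplitude); chromophore recordings use dataType 99999
(processed) with dataTypeLabel ``HbO``/``HbR``.

Channel labels are stored in the optional metadata tag ``channelLabels``
so that round trips preserve them exactly; files from other writers fall
back to ``S<i>-D<j>`` labels built from the measurement list.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np

from ..stimuli import StimulusEvent
from ..synthetic import Modality, TimeSeriesRecording

__all__ = ["write_fnirs", "read_fnirs"]

_CW_AMPLITUDE = 1
_PROCESSED = 99999


def _site_indices(label: str, fallback: int) -> tuple[int, int]:
    m = re.match(r"S(\d+)[-_]?D(\d+)", label)
    if m:
        return int(m.group(1)), int(m.group(2))
    return fallback, fallback


def write_fnirs(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a raw-intensity or chromophore recording as SNIRF."""
    if rec.modality not in (Modality.FNIRS_RAW, Modality.FNIRS_CHROMOPHORE):
        raise ValueError("write_fnirs expects an fNIRS recording")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="2000-01-01")
        meta.create_dataset("MeasurementTime", data="00:00:00")
        meta.create_dataset("LengthUnit", data="m")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset(
            "channelLabels", data=np.array(rec.channel_labels, dtype=object)
        )

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data.T)
        data.create_dataset("time", data=rec.times)

        sources: list[int] = []
        detectors: list[int] = []
        for i, label in enumerate(rec.channel_labels):
            site = label.rsplit(" ", 1)[0] if rec.modality is Modality.FNIRS_CHROMOPHORE else label
            s, d = _site_indices(site, i + 1)
            sources.append(s)
            detectors.append(d)
            ml = data.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=s)
            ml.create_dataset("detectorIndex", data=d)
            if rec.modality is Modality.FNIRS_RAW:
                ml.create_dataset("dataType", data=_CW_AMPLITUDE)
                ml.create_dataset("wavelengthIndex", data=1)
            else:
                ml.create_dataset("dataType", data=_PROCESSED)
                ml.create_dataset("wavelengthIndex", data=1)
                ml.create_dataset("dataTypeLabel", data=label.rsplit(" ", 1)[-1])
            ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=[760.0, 850.0])
        n_src, n_det = max(sources), max(detectors)
        probe.create_dataset(
            "sourcePos2D", data=np.column_stack([np.arange(n_src), np.zeros(n_src)])
        )
        probe.create_dataset(
            "detectorPos2D", data=np.column_stack([np.arange(n_det), np.ones(n_det)])
        )

        groups: dict[tuple[str, float], list[StimulusEvent]] = {}
        for e in rec.events:
            groups.setdefault((e.kind, e.intensity), []).append(e)
        for i, ((kind, level), evs) in enumerate(sorted(groups.items()), start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=f"{kind}@{level:g}")
            stim.create_dataset(
                "data", data=[[e.onset, e.duration, e.intensity] for e in evs]
            )


def _read_scalar(ds) -> object:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else v


def read_fnirs(path: str | Path) -> TimeSeriesRecording:
    """Read a SNIRF file; modality is set from the measurement-list
    dataType codes (1 -> raw intensity, 99999 HbO/HbR -> chromophore)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"]).T
        time = np.asarray(data["time"])
        if time.size == 2 and series.shape[1] > 2:
            fs = 1.0 / (time[1] - time[0])
        else:
            fs = 1.0 / np.median(np.diff(time))

        ml_names = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        dtypes, labels_from_ml = [], []
        for name in ml_names:
            ml = data[name]
            code = int(ml["dataType"][()])
            dtypes.append(code)
            site = f"S{int(ml['sourceIndex'][()])}-D{int(ml['detectorIndex'][()])}"
            if code == _PROCESSED:
                site += " " + str(_read_scalar(ml["dataTypeLabel"]))
            labels_from_ml.append(site)

        unsupported = {c for c in dtypes if c not in (_CW_AMPLITUDE, _PROCESSED)}
        if unsupported:
            raise ValueError(f"unsupported SNIRF dataType code(s): {sorted(unsupported)}")
        if len(set(dtypes)) > 1:
            raise ValueError("mixed raw/processed data blocks are not supported")
        if dtypes[0] == _PROCESSED:
            chrom = {lb.rsplit(" ", 1)[-1] for lb in labels_from_ml}
            if "HbO" in chrom and "HbR" not in chrom:
                raise ValueError("concentration file lacks HbR channels")
            modality = Modality.FNIRS_CHROMOPHORE
        else:
            modality = Modality.FNIRS_RAW

        meta = nirs.get("metaDataTags")
        if meta is not None and "channelLabels" in meta:
            labels = [
                v.decode() if isinstance(v, bytes) else str(v)
                for v in meta["channelLabels"][()]
            ]
        else:
            labels = labels_from_ml

        events = []
        for key in nirs:
            if not key.startswith("stim"):
                continue
            stim = nirs[key]
            name = str(_read_scalar(stim["name"]))
            kind = name.partition("@")[0]
            if kind not in ("click", "warble", "silence"):
                kind = "warble"
            for onset, duration, value in np.atleast_2d(np.asarray(stim["data"])):
                events.append(StimulusEvent(float(onset), float(duration), float(value), kind))
        events.sort(key=lambda e: e.onset)

    return TimeSeriesRecording(float(fs), labels, series, events, modality)
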