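"""Persistence for continuous and event streams.

The on-disk format is deliberately simple and self-describing: a one-line
JSON header (magic tag, version, stream kind, channel count, sample rate,
start sample, payload dtype/shape) terminated by a newline, followed by a
little-endian binary payload.  Continuous streams store a channel-major
float64 grid; event streams store typed records.  Every writer can also emit
a CSV mirror for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DigitalEvent, MultiChannelWindow, SpikeEvent, StimulusEvent, TimeBase

__all__ = ["StreamFileHeader", "write_stream", "read_stream",
           "write_events_csv", "read_events_csv"]

MAGIC = "NLSTREAM"
VERSION = 1

CONTINUOUS_KINDS = {"raw", "spike_band", "lfp", "mua"}
EVENT_KINDS = {"spikes", "stim", "digital"}

_EVENT_DTYPES = {
    "spikes": np.dtype([("time", "<i8"), ("channel", "<i4"), ("unit", "<i4")]),
    "stim": np.dtype([("time", "<i8"), ("channel", "<i4"),
                      ("amplitude", "<f8"), ("phase_width", "<f8")]),
    "digital": np.dtype([("time", "<i8"), ("port_state", "<u4")]),
}


@dataclass
class StreamFileHeader:
    stream_kind: str
    n_channels: int
    sample_rate: float
    start_sample: int = 0
    magic: str = MAGIC
    version: int = VERSION
    n_samples: int = 0
    n_events: int = 0

    def validate(self) -> None:
        if self.magic != MAGIC:
            raise ValueError(f"bad magic tag {self.magic!r}: not a stream file")
        if self.version != VERSION:
            raise ValueError(
                f"unsupported stream file version {self.version} "
                f"(reader supports {VERSION})")
        if self.stream_kind not in CONTINUOUS_KINDS | EVENT_KINDS:
            raise ValueError(f"unknown stream kind {self.stream_kind!r}")


def _events_to_records(kind: str, events: list) -> np.ndarray:
    dt = _EVENT_DTYPES[kind]
    rec = np.empty(len(events), dtype=dt)
    if kind == "spikes":
        for i, e in enumerate(events):
            rec[i] = (e.time, e.channel, e.unit)
    elif kind == "stim":
        for i, e in enumerate(events):
            rec[i] = (e.time, e.channel, e.amplitude, e.phase_width)
    else:
        for i, e in enumerate(events):
            rec[i] = (e.time, e.port_state)
    return rec


def _records_to_events(kind: str, rec: np.ndarray) -> list:
    if kind == "spikes":
        return [SpikeEvent(time=int(r["time"]), channel=int(r["channel"]),
                           unit=int(r["unit"])) for r in rec]
    if kind == "stim":
        return [StimulusEvent(time=int(r["time"]), channel=int(r["channel"]),
                              amplitude=float(r["amplitude"]),
                              phase_width=float(r["phase_width"])) for r in rec]
    return [DigitalEvent(time=int(r["time"]), port_state=int(r["port_state"]))
            for r in rec]


def write_stream(path: str | Path, header: StreamFileHeader, payload,
                 csv_mirror: bool = False) -> Path:
    """Write a stream file; optionally also a ``.csv`` mirror next to it."""
    path = Path(path)
    header.validate()
    try:
        if header.stream_kind in CONTINUOUS_KINDS:
            window: MultiChannelWindow = payload
            if window.n_channels != header.n_channels:
                raise ValueError("payload channel count disagrees with header")
            header.n_samples = window.n_samples
            body = window.values.astype("<f8").tobytes()
        else:
            rec = _events_to_records(header.stream_kind, payload)
            header.n_events = len(rec)
            body = rec.tobytes()
        with open(path, "wb") as fh:
            fh.write((json.dumps(asdict(header)) + "\n").encode())
            fh.write(body)
        if csv_mirror:
            _write_csv_mirror(path.with_suffix(path.suffix + ".csv"),
                              header, payload)
    except OSError as exc:
        raise OSError(f"failed writing stream file {path}: {exc}") from exc
    return path


def _write_csv_mirror(path: Path, header: StreamFileHeader, payload) -> None:
    fs = header.sample_rate
    if header.stream_kind in CONTINUOUS_KINDS:
        df = pd.DataFrame(payload.values.T,
                          columns=[f"ch{c}" for c in range(header.n_channels)])
        df.insert(0, "time_s", (payload.start_sample + np.arange(len(df))) / fs)
    elif header.stream_kind == "spikes":
        df = pd.DataFrame([(e.time / fs, e.channel, e.unit) for e in payload],
                          columns=["time_s", "channel", "unit"])
    elif header.stream_kind == "stim":
        df = pd.DataFrame(
            [(e.time / fs, e.channel, e.amplitude, e.phase_width) for e in payload],
            columns=["time_s", "channel", "amplitude_v", "phase_width_s"])
    else:
        df = pd.DataFrame([(e.time / fs, e.port_state) for e in payload],
                          columns=["time_s", "port_state"])
    df.to_csv(path, index=False)


def read_stream(path: str | Path) -> tuple[StreamFileHeader, object]:
    """Inverse of :func:`write_stream`."""
    path = Path(path)
    with open(path, "rb") as fh:
        header_line = fh.readline()
        try:
            hd = StreamFileHeader(**json.loads(header_line))
        except (json.JSONDecodeError, TypeError) as exc:
            raise ValueError(f"{path}: corrupt or missing stream header") from exc
        hd.validate()
        body = fh.read()
    if hd.stream_kind in CONTINUOUS_KINDS:
        expected = hd.n_channels * hd.n_samples * 8
        if len(body) != expected:
            raise ValueError(
                f"{path}: truncated payload, expected {expected} bytes, "
                f"found {len(body)}")
        vals = np.frombuffer(body, dtype="<f8").reshape(hd.n_channels, hd.n_samples)
        window = MultiChannelWindow(hd.start_sample, vals.copy(),
                                    TimeBase(hd.sample_rate))
        return hd, window
    dt = _EVENT_DTYPES[hd.stream_kind]
    expected = hd.n_events * dt.itemsize
    if len(body) != expected:
        raise ValueError(f"{path}: truncated payload, expected {expected} "
                         f"bytes, found {len(body)}")
    rec = np.frombuffer(body, dtype=dt)
    return hd, _records_to_events(hd.stream_kind, rec)


def write_events_csv(path: str | Path, kind: str, events: list,
                     sample_rate: float) -> Path:
    hd = StreamFileHeader(stream_kind=kind, n_channels=0,
                          sample_rate=sample_rate)
    _write_csv_mirror(Path(path), hd, events)
    return Path(path)


def read_events_csv(path: str | Path, kind: str, sample_rate: float) -> list:
    df = pd.read_csv(path)
    if kind == "spikes":
        return [SpikeEvent(time=int(round(r.time_s * sample_rate)),
                           channel=int(r.channel), unit=int(r.unit))
                for r in df.itertuples()]
    if kind == "stim":
        return [StimulusEvent(time=int(round(r.time_s * sample_rate)),
                              channel=int(r.channel),
                              amplitude=float(r.amplitude_v),
                              phase_width=float(r.phase_width_s))
                for r in df.itertuples()]
    return [DigitalEvent(time=int(round(r.time_s * sample_rate)),
                         port_state=int(r.port_state)) for r in df.itertuples()]
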