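"""Time-series containers and plain-text trace I/O.

The interchange format is CSV: first column ``time [s]``, remaining
columns ``name [unit]``.  Metadata (seed, config hash, stage) travels in
a JSON sidecar next to the CSV.  Missing cells become NaN on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError

_HEADER_RE = re.compile(r"^\s*(?P<name>[^\[\]]+?)\s*\[(?P<unit>[^\[\]]*)\]\s*$")


@dataclass
class TimeSeries:
    """A single named channel on a time base in seconds."""

    time: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise TraceFormatError(
                f"time and values differ in length for channel '{self.name}'")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise TraceFormatError(f"time not strictly increasing in '{self.name}'")

    def __len__(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        if len(self) < 2:
            raise TraceFormatError("sample rate undefined for < 2 samples")
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class MultiChannelTrace:
    """Timestamped multichannel series with per-channel units.

    ``channels`` maps name -> values (equal length to ``time``); ``units``
    maps name -> nonempty unit string.  ``metadata`` is free-form
    provenance (seed, config hash, stage name).
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise TraceFormatError("time must be one-dimensional")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise TraceFormatError("time not strictly increasing")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vals in self.channels.items():
            if vals.shape != self.time.shape:
                raise TraceFormatError(f"channel '{name}' length mismatch")
            if name not in self.units or not str(self.units[name]).strip():
                raise TraceFormatError(f"channel '{name}' has no unit")

    def __len__(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        if len(self) < 2:
            raise TraceFormatError("sample rate undefined for < 2 samples")
        return 1.0 / float(np.median(np.diff(self.time)))

    def series(self, name: str) -> TimeSeries:
        return TimeSeries(self.time, self.channels[name], self.units[name], name)

    def with_channel(self, name: str, values: np.ndarray, unit: str) -> "MultiChannelTrace":
        channels = dict(self.channels)
        units = dict(self.units)
        channels[name] = np.asarray(values, dtype=float)
        units[name] = unit
        return MultiChannelTrace(self.time, channels, units, dict(self.metadata))


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_trace(trace: MultiChannelTrace, path: str | Path) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar.

    Column order is deterministic (time first, channels in insertion
    order); floats are written with full round-trip precision.
    """
    path = Path(path)
    cols = {"time [s]": trace.time}
    for name, vals in trace.channels.items():
        cols[f"{name} [{trace.units[name]}]"] = vals
    df = pd.DataFrame(cols)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar_path(path).write_text(json.dumps(trace.metadata, indent=2, sort_keys=True))
    except OSError as exc:  # unwritable path
        raise TraceFormatError(f"cannot write trace to {path}: {exc}") from exc


def read_trace(path: str | Path) -> MultiChannelTrace:
    """Read a CSV trace; enforces header units and strictly increasing time."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise TraceFormatError(f"cannot read trace from {path}: {exc}") from exc

    if df.shape[1] < 1:
        raise TraceFormatError(f"{path}: no columns")

    names, units = [], []
    for col in df.columns:
        m = _HEADER_RE.match(col)
        if not m or not m.group("unit").strip():
            raise TraceFormatError(f"{path}: column '{col}' lacks a 'name [unit]' header")
        names.append(m.group("name").strip())
        units.append(m.group("unit").strip())
    if names[0] != "time" or units[0] != "s":
        raise TraceFormatError(f"{path}: first column must be 'time [s]'")

    time = df.iloc[:, 0].to_numpy(dtype=float)
    if time.size > 1 and not np.all(np.diff(time) > 0):
        raise TraceFormatError(f"{path}: time not strictly increasing")

    channels = {n: df.iloc[:, i].to_numpy(dtype=float)
                for i, n in enumerate(names) if i > 0}
    unit_map = {n: u for n, u in zip(names[1:], units[1:])}

    metadata: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        metadata = json.loads(sc.read_text())
    return MultiChannelTrace(time, channels, unit_map, metadata)
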