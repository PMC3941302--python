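"""Open on-disk format for continuous performance recordings and feature tables.

The proprietary format of commercial reproducing-piano systems is undocumented,
so recordings are stored in an open two-file layout:

* ``<stem>.json`` — sidecar metadata: format version, sampling rate, performer /
  piece / timbre / repetition labels, hammer events and the trace column list;
* ``<stem>.csv`` — columnar integer payload, one column per active key
  (``k<midi>``) plus the two pedals (``soft``, ``sust``); the time base is
  implicit from the rate (sample ``i`` is at ``i * 1000 / rate`` ms).

Positions are 8-bit steps in [0, 250]; 0 is the key (or pedal) at rest and 250
fully depressed.  The round trip is bit-exact on integer traces.

Feature tables are stored as CSV with a JSON schema sidecar that pins the
column order; missing values survive the round trip as missing, never as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema

__all__ = [
    "FORMAT_VERSION",
    "HammerEvent",
    "PerformanceRecording",
    "RecordingError",
    "SchemaMismatchError",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
    "METADATA_COLUMNS",
]

FORMAT_VERSION = 1
PEDALS = ("soft", "sust")
METADATA_COLUMNS = ("pianist", "piece", "timbre", "repetition")


class RecordingError(ValueError):
    """Malformed recording (parse or validation failure); names the field."""


class SchemaMismatchError(ValueError):
    """Feature table columns disagree with the frozen schema."""


@dataclass(frozen=True)
class HammerEvent:
    pitch: int
    time_ms: float
    mhv: int


@dataclass
class PerformanceRecording:
    """Time-aligned key and pedal position traces plus hammer events.

    ``key_traces`` maps MIDI pitch to an integer position series; all series
    (keys and pedals) share one time base at ``rate`` Hz.
    """

    pianist: str
    piece: str
    timbre: str
    repetition: int
    rate: float = 500.0
    key_traces: dict = field(default_factory=dict)
    pedal_traces: dict = field(default_factory=dict)
    hammer_events: list = field(default_factory=list)

    def __post_init__(self):
        for name in PEDALS:
            if name not in self.pedal_traces:
                self.pedal_traces[name] = np.zeros(self.n_samples, dtype=np.int16)
        self.validate()

    # ------------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        for trace in self.key_traces.values():
            return len(trace)
        for trace in self.pedal_traces.values():
            return len(trace)
        return 0

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.rate

    @property
    def dt_ms(self) -> float:
        """Sample period in ms (2 ms at the default 500 Hz)."""
        return 1000.0 / self.rate

    def validate(self) -> None:
        if self.rate <= 0:
            raise RecordingError(f"rate must be positive, got {self.rate}")
        n = self.n_samples
        for label, trace in list(self.key_traces.items()) + list(self.pedal_traces.items()):
            arr = np.asarray(trace)
            if len(arr) != n:
                raise RecordingError(
                    f"trace {label!r} has {len(arr)} samples, expected {n}"
                )
            if arr.size and (arr.min() < 0 or arr.max() > 250):
                raise RecordingError(
                    f"trace {label!r} has positions outside [0, 250]"
                )
        if self.hammer_events and not self.key_traces:
            raise RecordingError("hammer_events present but key_traces empty")
        span = self.duration_ms
        for ev in self.hammer_events:
            if not (0 <= ev.time_ms <= span):
                raise RecordingError(
                    f"hammer event at {ev.time_ms} ms outside recording span {span} ms"
                )
            if not (0 <= ev.mhv <= 250):
                raise RecordingError(f"hammer MHV {ev.mhv} outside [0, 250]")

    def __eq__(self, other):
        if not isinstance(other, PerformanceRecording):
            return NotImplemented
        meta = all(
            getattr(self, k) == getattr(other, k)
            for k in ("pianist", "piece", "timbre", "repetition", "rate")
        )
        keys = set(self.key_traces) == set(other.key_traces) and all(
            np.array_equal(self.key_traces[p], other.key_traces[p]) for p in self.key_traces
        )
        pedals = all(
            np.array_equal(self.pedal_traces[p], other.pedal_traces[p]) for p in PEDALS
        )
        return meta and keys and pedals and self.hammer_events == other.hammer_events


# ---------------------------------------------------------------------------
# recording round trip
# ---------------------------------------------------------------------------


def _paths(path) -> tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix in (".json", ".csv"):
        stem = stem.with_suffix("")
    return stem.with_suffix(".json"), stem.with_suffix(".csv")


def write_recording(rec: PerformanceRecording, path) -> None:
    """Write ``rec`` to ``<path>.json`` + ``<path>.csv`` (lossless)."""
    rec.validate()
    meta_path, csv_path = _paths(path)
    columns = [f"k{p}" for p in sorted(rec.key_traces)] + list(PEDALS)
    meta = {
        "format_version": FORMAT_VERSION,
        "pianist": rec.pianist,
        "piece": rec.piece,
        "timbre": rec.timbre,
        "repetition": rec.repetition,
        "rate": rec.rate,
        "columns": columns,
        "n_samples": rec.n_samples,
        "hammer_events": [[ev.pitch, ev.time_ms, ev.mhv] for ev in rec.hammer_events],
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    data = {f"k{p}": np.asarray(rec.key_traces[p], dtype=np.int16) for p in sorted(rec.key_traces)}
    for name in PEDALS:
        data[name] = np.asarray(rec.pedal_traces[name], dtype=np.int16)
    pd.DataFrame(data).to_csv(csv_path, index=False)


def read_recording(path) -> PerformanceRecording:
    """Read a recording written by :func:`write_recording`."""
    meta_path, csv_path = _paths(path)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise RecordingError(f"malformed metadata header in {meta_path}: {exc}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise RecordingError(
            f"format_version: expected {FORMAT_VERSION}, got {version!r}"
        )
    for key in ("pianist", "piece", "timbre", "repetition", "rate", "columns", "n_samples"):
        if key not in meta:
            raise RecordingError(f"missing metadata field {key!r}")
    frame = pd.read_csv(csv_path)
    if list(frame.columns) != list(meta["columns"]):
        raise RecordingError(
            f"columns: payload {list(frame.columns)} != header {meta['columns']}"
        )
    if len(frame) != meta["n_samples"]:
        raise RecordingError(
            f"n_samples: payload has {len(frame)}, header says {meta['n_samples']}"
        )
    key_traces = {}
    pedal_traces = {}
    for col in frame.columns:
        values = frame[col].to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise RecordingError(f"trace {col!r} contains non-integer positions")
        arr = values.astype(np.int16)
        if col.startswith("k"):
            key_traces[int(col[1:])] = arr
        elif col in PEDALS:
            pedal_traces[col] = arr
        else:
            raise RecordingError(f"unknown trace column {col!r}")
    events = [HammerEvent(int(p), float(t), int(v)) for p, t, v in meta["hammer_events"]]
    return PerformanceRecording(
        pianist=meta["pianist"],
        piece=meta["piece"],
        timbre=meta["timbre"],
        repetition=int(meta["repetition"]),
        rate=float(meta["rate"]),
        key_traces=key_traces,
        pedal_traces=pedal_traces,
        hammer_events=events,
    )


# ---------------------------------------------------------------------------
# feature table round trip
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path, schema: FeatureSchema | None = None) -> None:
    """Write a performances x features table as CSV plus a JSON schema sidecar.

    Column order follows the frozen schema; metadata columns come first.
    Values are written at full precision; missing stays missing.
    """
    schema = schema or default_schema()
    path = Path(path)
    cols = [c for c in METADATA_COLUMNS if c in table.columns]
    cols += [c for c in schema.column_names if c in table.columns]
    unknown = [c for c in table.columns if c not in cols]
    if unknown:
        raise SchemaMismatchError(f"unknown feature columns: {unknown[:5]}")
    table = table[cols]
    table.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "format_version": FORMAT_VERSION,
        "metadata_columns": [c for c in METADATA_COLUMNS if c in cols],
        "feature_columns": [c for c in cols if c not in METADATA_COLUMNS],
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path, schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Read a feature table, checking every column against the schema."""
    schema = schema or default_schema()
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".schema.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("format_version") != FORMAT_VERSION:
            raise RecordingError(
                f"format_version: expected {FORMAT_VERSION}, got {sidecar.get('format_version')!r}"
            )
    frame = pd.read_csv(path)
    known = set(schema.column_names) | set(METADATA_COLUMNS)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise SchemaMismatchError(f"unknown feature columns: {unknown[:5]}")
    feature_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    frame[feature_cols] = frame[feature_cols].astype(float)
    return frame
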