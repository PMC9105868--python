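"""Reading, cleaning and framing of multi-sensor pressure recordings.

A recording is a table of synchronized pressure readings (kPa): one row per
time sample, one column per labeled sensor.  On disk it is a plain CSV with
a header of sensor labels, optionally accompanied by a sidecar JSON
(``<stem>.json``) carrying the sampling rate and the device reading range.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_SAMPLING_RATE",
    "DEFAULT_READING_RANGE",
    "FormatError",
    "SensorRecording",
    "Frame",
    "read_recording",
    "write_recording",
    "clean",
    "slice_frames",
]

DEFAULT_SAMPLING_RATE = 100.0
DEFAULT_READING_RANGE = (0.0, 64.0)


class FormatError(ValueError):
    """Malformed input data (ragged rows, non-numeric cells, bad labels)."""


@dataclass(frozen=True)
class SensorRecording:
    """A labeled multi-sensor pressure time series.

    Parameters
    ----------
    sensor_labels
        Unique sensor names, in column order.
    readings
        Pressure matrix of shape ``(n_samples, n_sensors)`` in kPa.  Values
        may lie outside ``reading_range`` on input; :func:`clean` clamps
        them before analysis.
    sampling_rate
        Samples per second, strictly positive.
    reading_range
        Closed device range ``(lo, hi)`` in kPa with ``lo < hi``.
    """

    sensor_labels: tuple[str, ...]
    readings: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    reading_range: tuple[float, float] = DEFAULT_READING_RANGE

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.sensor_labels)
        object.__setattr__(self, "sensor_labels", labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate sensor labels: {dupes}")
        data = np.asarray(self.readings, dtype=float)
        if data.ndim != 2:
            raise FormatError(f"readings must be 2-D, got shape {data.shape}")
        if data.shape[1] != len(labels):
            raise FormatError(
                f"readings have {data.shape[1]} columns for {len(labels)} labels"
            )
        if not np.all(np.isfinite(data)):
            t, s = np.argwhere(~np.isfinite(data))[0]
            raise FormatError(
                f"non-finite reading at sample {t}, sensor {labels[s]!r}"
            )
        data = data.copy()
        data.flags.writeable = False
        object.__setattr__(self, "readings", data)
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        lo, hi = (float(v) for v in self.reading_range)
        if not lo < hi:
            raise ValueError(f"reading_range must satisfy lo < hi, got {(lo, hi)}")
        object.__setattr__(self, "reading_range", (lo, hi))

    @property
    def n_samples(self) -> int:
        return self.readings.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.readings.shape[1]

    def column(self, label: str) -> np.ndarray:
        """Return one sensor's series by label."""
        try:
            idx = self.sensor_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown sensor label {label!r}") from None
        return self.readings[:, idx]

    def indices_of(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.sensor_labels.index(str(l)) for l in labels])


@dataclass(frozen=True)
class Frame:
    """One contiguous, half-open window ``[start, start+length)`` of a recording."""

    source: str
    start_index: int
    data: np.ndarray = field(repr=False)
    sensor_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("frame needs a 2-D block of at least 2 samples")
        if not np.all(np.isfinite(data)):
            raise ValueError("frame contains non-finite values")
        data = data.copy()
        data.flags.writeable = False
        object.__setattr__(self, "data", data)
        object.__setattr__(
            self, "sensor_labels", tuple(str(l) for l in self.sensor_labels)
        )
        if len(self.sensor_labels) != data.shape[1]:
            raise ValueError("one label per frame column required")

    @property
    def length(self) -> int:
        return self.data.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            idx = self.sensor_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown sensor label {label!r}") from None
        return self.data[:, idx]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(
    path: str | Path,
    *,
    scale: float = 1.0,
    sampling_rate: float | None = None,
    reading_range: tuple[float, float] | None = None,
) -> SensorRecording:
    """Read a recording from CSV (header = sensor labels, one row per sample).

    ``scale`` multiplies every value (e.g. ``0.001`` for Pa input).  Sampling
    rate and reading range come from the arguments if given, otherwise from
    the ``<stem>.json`` sidecar, otherwise the 100 Hz / 0-64 kPa defaults.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        labels = tuple(h.strip() for h in header)
        if len(set(labels)) != len(labels):
            raise FormatError(f"{path}: duplicate sensor labels in header")
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(labels):
                raise FormatError(
                    f"{path}: row {lineno} has {len(row)} cells, expected {len(labels)}"
                )
            parsed = []
            for col, cell in zip(labels, row):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno},"
                        f" column {col!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no data rows")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists() and sidecar != path:
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if sampling_rate is None:
        sampling_rate = float(meta.get("sampling_rate", DEFAULT_SAMPLING_RATE))
    if reading_range is None:
        rr = meta.get("reading_range", DEFAULT_READING_RANGE)
        reading_range = (float(rr[0]), float(rr[1]))

    readings = np.asarray(rows, dtype=float) * float(scale)
    return SensorRecording(
        sensor_labels=labels,
        readings=readings,
        sampling_rate=sampling_rate,
        reading_range=reading_range,
    )


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write CSV plus ``<stem>.json`` sidecar; round-trips full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.sensor_labels)
        for row in rec.readings:
            writer.writerow([repr(float(v)) for v in row])
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "sampling_rate": rec.sampling_rate,
                "reading_range": list(rec.reading_range),
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


def clean(rec: SensorRecording) -> SensorRecording:
    """Clamp every reading into the device range. Idempotent."""
    lo, hi = rec.reading_range
    return SensorRecording(
        sensor_labels=rec.sensor_labels,
        readings=np.clip(rec.readings, lo, hi),
        sampling_rate=rec.sampling_rate,
        reading_range=rec.reading_range,
    )


def slice_frames(
    rec: SensorRecording, frame_length: int, *, source: str = "recording"
) -> list[Frame]:
    """Cut the recording into consecutive, non-overlapping, equal-length frames.

    Returns ``floor(T / frame_length)`` frames starting at sample 0; a
    trailing remainder shorter than ``frame_length`` is discarded.
    """
    if frame_length < 2:
        raise ValueError(f"frame_length must be >= 2, got {frame_length}")
    T = rec.n_samples
    if frame_length > T:
        raise ValueError(
            f"no complete frame: frame_length {frame_length} exceeds {T} samples"
        )
    n_frames = T // frame_length
    return [
        Frame(
            source=source,
            start_index=i * frame_length,
            data=rec.readings[i * frame_length : (i + 1) * frame_length],
            sensor_labels=rec.sensor_labels,
        )
        for i in range(n_frames)
    ]
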