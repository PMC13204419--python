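"""Telemetry record schema, CSV I/O and the temperature safety monitor.

One :class:`TelemetryRecord` is a single synchronized optical+thermal sensor
sample — the unit of both simulated and ingested data. CSV with a fixed
header is the single interchange format: data volumes are tiny and human
inspection matters for a monitoring tool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TelemetryRecord",
    "COLUMNS",
    "write_telemetry",
    "read_telemetry",
    "records_to_frame",
    "SafetyEvent",
    "safety_monitor",
]

logger = logging.getLogger(__name__)

COLUMNS = [
    "timestamp_s",
    "wavelength_nm",
    "detector_id",
    "distance_mm",
    "flux",
    "gain",
    "integration_ms",
    "temp_c",
]

_DETECTOR_IDS = {"near", "far"}


@dataclass(frozen=True)
class TelemetryRecord:
    """One synchronized sensor sample.

    ``flux`` is the photodetector reading in arbitrary linear units;
    ``temp_c`` is the surface temperature and may be NaN on optical-only
    frames.
    """

    timestamp_s: float
    wavelength_nm: float
    detector_id: str
    distance_mm: float
    flux: float
    gain: float = 1.0
    integration_ms: float = 100.0
    temp_c: float = math.nan

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError(f"flux must be >= 0, got {self.flux}")
        if self.distance_mm <= 0:
            raise ValueError(f"distance_mm must be > 0, got {self.distance_mm}")
        if self.detector_id not in _DETECTOR_IDS:
            raise ValueError(f"detector_id must be one of {_DETECTOR_IDS}, got {self.detector_id!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Materialize a record stream as a DataFrame with the canonical columns."""
    return pd.DataFrame([asdict(r) for r in records], columns=COLUMNS)


def write_telemetry(records, path) -> None:
    """Write records to CSV at full float precision (lossless round trip)."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_telemetry(path) -> list[TelemetryRecord]:
    """Read and validate a telemetry CSV.

    Malformed rows (non-numeric fields, negative flux, bad detector id) are
    skipped with a logged count. Out-of-order timestamps are re-sorted with a
    warning. Missing mandatory columns or an empty file are hard errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"telemetry file {path} is empty") from exc
    if df.empty:
        raise ValueError(f"telemetry file {path} contains no records")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry file {path} lacks mandatory columns: {missing}")

    records: list[TelemetryRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            records.append(
                TelemetryRecord(
                    timestamp_s=float(row["timestamp_s"]),
                    wavelength_nm=float(row["wavelength_nm"]),
                    detector_id=str(row["detector_id"]),
                    distance_mm=float(row["distance_mm"]),
                    flux=float(row["flux"]),
                    gain=float(row["gain"]),
                    integration_ms=float(row["integration_ms"]),
                    temp_c=float(row["temp_c"]),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed telemetry row %d: %s", idx, exc)
    if n_skipped:
        logger.warning("skipped %d malformed row(s) in %s", n_skipped, path)
    if not records:
        raise ValueError(f"telemetry file {path} contains no valid records")

    times = [r.timestamp_s for r in records]
    if any(b < a for a, b in zip(times, times[1:])):
        logger.warning("timestamps in %s are not non-decreasing; re-sorting", path)
        records.sort(key=lambda r: r.timestamp_s)
    return records


@dataclass(frozen=True)
class SafetyEvent:
    """Light-source shutoff triggered by a temperature excursion."""

    index: int
    timestamp_s: float
    temp_c: float
    threshold_c: float


def safety_monitor(temp_stream, threshold: float = 43.0):
    """Scan a temperature series for over-threshold excursions.

    Fires one :class:`SafetyEvent` at the first sample *strictly* exceeding
    ``threshold`` within each contiguous excursion (a sample exactly at the
    threshold does not fire). Returns ``(events, source_on)`` where
    ``source_on`` is a boolean array that goes (and stays) False from the
    first event onward — the light source is shut off and not re-armed.

    ``temp_stream`` is a sequence of (timestamp_s, temp_c) pairs, a mapping
    with those keys, or a DataFrame with those columns.
    """
    if not math.isfinite(threshold):
        raise ValueError("safety threshold must be finite")
    if isinstance(temp_stream, pd.DataFrame):
        pairs = list(zip(temp_stream["timestamp_s"], temp_stream["temp_c"]))
    else:
        pairs = [(float(t), float(T)) for t, T in temp_stream]

    events: list[SafetyEvent] = []
    source_on = np.ones(len(pairs), dtype=bool)
    in_excursion = False
    tripped = False
    for i, (t, T) in enumerate(pairs):
        exceeding = T > threshold
        if exceeding and not in_excursion:
            events.append(SafetyEvent(index=i, timestamp_s=t, temp_c=T, threshold_c=threshold))
            tripped = True
        in_excursion = exceeding
        if tripped:
            source_on[i] = False
    return events, source_on
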