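"""Data model and I/O for footprint and trackway measurements.

A *trackway* is an ordered sequence of footprints attributed to a single
individual moving across a surface.  Lengths are stored in millimetres,
velocities in metres per second, and compass orientations in degrees
clockwise from north in ``[0, 360)``.  The relative stride length (RSL,
median stride length divided by median footprint length) is the
dimensionless gait indicator used throughout: walking humans cluster
near 5-6, runners well above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "FootprintMeasurement",
    "Trackway",
    "TrackwaySummary",
    "TableSchema",
    "ValidationError",
    "SchemaError",
    "read_trackway_table",
    "write_trackway_table",
    "summarize_trackway",
    "mm_to_m",
    "m_to_mm",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ValidationError(ValueError):
    """A measurement violates its physical constraints."""


def mm_to_m(x: float) -> float:
    """Convert millimetres to metres."""
    return x / 1000.0


def m_to_mm(x: float) -> float:
    """Convert metres to millimetres."""
    return x * 1000.0


@dataclass(frozen=True)
class FootprintMeasurement:
    """One footprint: heel-to-hallux length plus optional breadths (mm)."""

    track_id: str
    length_mm: float
    forefoot_breadth_mm: Optional[float] = None
    heel_breadth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValidationError(
                f"footprint {self.track_id!r}: length must be positive, "
                f"got {self.length_mm}"
            )
        for name in ("forefoot_breadth_mm", "heel_breadth_mm"):
            val = getattr(self, name)
            if val is not None and not 0 < val < self.length_mm:
                raise ValidationError(
                    f"footprint {self.track_id!r}: {name}={val} must be in "
                    f"(0, length={self.length_mm})"
                )


@dataclass
class Trackway:
    """An ordered footprint sequence with strides and a compass bearing.

    Merged identifiers such as ``"C/G"`` denote two excavated segments
    treated as a single trackway.
    """

    trackway_id: str
    footprints: list[FootprintMeasurement]
    stride_lengths_mm: list[float] = field(default_factory=list)
    compass_deg: Optional[float] = None
    direction_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.footprints:
            raise ValidationError(
                f"trackway {self.trackway_id!r}: needs at least one footprint"
            )
        for s in self.stride_lengths_mm:
            if not s > 0:
                raise ValidationError(
                    f"trackway {self.trackway_id!r}: stride {s} must be > 0"
                )
        if self.compass_deg is not None and not 0 <= self.compass_deg < 360:
            raise ValidationError(
                f"trackway {self.trackway_id!r}: compass {self.compass_deg} "
                "outside [0, 360)"
            )


@dataclass(frozen=True)
class TrackwaySummary:
    """Per-trackway medians used by downstream estimators."""

    trackway_id: str
    median_footprint_length_mm: float
    relative_stride_length: Optional[float] = None
    median_forefoot_breadth_mm: Optional[float] = None
    median_heel_breadth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.relative_stride_length is not None and not self.relative_stride_length > 0:
            raise ValidationError(
                f"trackway {self.trackway_id!r}: relative stride length must be > 0"
            )


@dataclass(frozen=True)
class TableSchema:
    """Column-name mapping for a delimited trackway table.

    ``level`` declares whether each row is one footprint
    (``"footprint"``) or one whole trackway (``"trackway"``).  Stride
    and compass columns may repeat within a trackway's footprint rows;
    the first non-missing value is taken, except strides, which are
    collected from every row that carries one.
    """

    level: str = "footprint"
    trackway_id: str = "trackway_id"
    length_mm: str = "length_mm"
    forefoot_breadth_mm: Optional[str] = None
    heel_breadth_mm: Optional[str] = None
    stride_mm: Optional[str] = None
    compass_deg: Optional[str] = None
    direction_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level not in ("footprint", "trackway"):
            raise SchemaError(f"unknown table level {self.level!r}")


def _opt_float(row: pd.Series, col: Optional[str], rownum: int) -> Optional[float]:
    if col is None or col not in row or pd.isna(row[col]):
        return None
    try:
        return float(row[col])
    except (TypeError, ValueError):
        raise ValidationError(f"row {rownum}: non-numeric value {row[col]!r} in {col!r}")


def read_trackway_table(path, schema: TableSchema = TableSchema(), sep: str = ",") -> list[Trackway]:
    """Parse a delimited footprint/trackway table into :class:`Trackway` objects.

    Raises :class:`SchemaError` if a mandatory column is absent and
    :class:`ValidationError` (naming the offending row) for non-numeric
    or out-of-range measurements.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (schema.trackway_id, schema.length_mm):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    order: list[str] = []
    prints: dict[str, list[FootprintMeasurement]] = {}
    strides: dict[str, list[float]] = {}
    compass: dict[str, Optional[float]] = {}
    labels: dict[str, Optional[str]] = {}

    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        tid = str(row[schema.trackway_id])
        if tid not in prints:
            order.append(tid)
            prints[tid], strides[tid] = [], []
            compass[tid], labels[tid] = None, None
        try:
            length = float(row[schema.length_mm])
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {rownum}: non-numeric footprint length {row[schema.length_mm]!r}"
            )
        try:
            fp = FootprintMeasurement(
                track_id=f"{tid}.{len(prints[tid]) + 1}",
                length_mm=length,
                forefoot_breadth_mm=_opt_float(row, schema.forefoot_breadth_mm, rownum),
                heel_breadth_mm=_opt_float(row, schema.heel_breadth_mm, rownum),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {rownum}: {exc}") from None
        prints[tid].append(fp)

        s = _opt_float(row, schema.stride_mm, rownum)
        if s is not None:
            strides[tid].append(s)
        c = _opt_float(row, schema.compass_deg, rownum)
        if c is not None:
            if not 0 <= c < 360:
                raise ValidationError(f"row {rownum}: compass {c} outside [0, 360)")
            if compass[tid] is None:
                compass[tid] = c
        if schema.direction_label and schema.direction_label in row:
            lab = row[schema.direction_label]
            if labels[tid] is None and not pd.isna(lab):
                labels[tid] = str(lab)

    return [
        Trackway(
            trackway_id=tid,
            footprints=prints[tid],
            stride_lengths_mm=strides[tid],
            compass_deg=compass[tid],
            direction_label=labels[tid],
        )
        for tid in order
    ]


def write_trackway_table(trackways: Sequence[Trackway], path, sep: str = ",") -> None:
    """Write trackways as a footprint-level table readable by
    :func:`read_trackway_table` with the default schema plus stride,
    compass and direction columns (round-trip safe)."""
    rows = []
    for t in trackways:
        for i, fp in enumerate(t.footprints):
            rows.append(
                {
                    "trackway_id": t.trackway_id,
                    "length_mm": fp.length_mm,
                    "forefoot_breadth_mm": fp.forefoot_breadth_mm,
                    "heel_breadth_mm": fp.heel_breadth_mm,
                    "stride_mm": t.stride_lengths_mm[i] if i < len(t.stride_lengths_mm) else None,
                    "compass_deg": t.compass_deg if i == 0 else None,
                    "direction_label": t.direction_label if i == 0 else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.12g")


ROUNDTRIP_SCHEMA = TableSchema(
    level="footprint",
    stride_mm="stride_mm",
    forefoot_breadth_mm="forefoot_breadth_mm",
    heel_breadth_mm="heel_breadth_mm",
    compass_deg="compass_deg",
    direction_label="direction_label",
)


def summarize_trackway(t: Trackway) -> TrackwaySummary:
    """Reduce a trackway to the medians used by the estimators.

    The median with an even count is the mean of the two central
    values.  The relative stride length is the median stride divided by
    the median footprint length; it is absent when no strides were
    measured.
    """
    lengths = [fp.length_mm for fp in t.footprints]
    med_len = median(lengths)
    rsl = None
    if t.stride_lengths_mm:
        rsl = median(t.stride_lengths_mm) / med_len
    fb = [fp.forefoot_breadth_mm for fp in t.footprints if fp.forefoot_breadth_mm is not None]
    hb = [fp.heel_breadth_mm for fp in t.footprints if fp.heel_breadth_mm is not None]
    return TrackwaySummary(
        trackway_id=t.trackway_id,
        median_footprint_length_mm=med_len,
        relative_stride_length=rsl,
        median_forefoot_breadth_mm=median(fb) if fb else None,
        median_heel_breadth_mm=median(hb) if hb else None,
    )
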