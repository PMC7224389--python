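"""Bundled Engare Sero trackway measurements.

The published study prints, per trackway, the relative stride length,
predicted gait and velocity, compass orientation, most-probable age/sex
attribution (23 trackways with measurable strides) and predicted
stature (25 trackways).  Those printed values are stored verbatim in
the two CSV files shipped here.

Per-trackway median footprint lengths are published only for the
largest trackway, D (289.5 mm).  The remaining medians returned by
:func:`engare_sero_fixture` are therefore a *synthetic reconstruction*:
each trackway's median is scaled from D's in proportion to its
published stature (median_i = 289.5 mm x stature_i / 1.83 m).  They
preserve the published size ranking and D's true value, and exist so
that size-dependent stages (stature ranking, group-structure windows)
can run end to end; they are not measurements.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from ..data import FootprintMeasurement, Trackway, TrackwaySummary

__all__ = [
    "engare_sero_fixture",
    "load_trackway_records",
    "load_stature_records",
    "NE_COMPASS_DEG",
    "SW_COMPASS_DEG",
    "LARGEST_MEDIAN_MM",
    "LARGEST_TRACKWAY_ID",
]

# Median footprint length of the largest trackway (D), mm — the one
# per-trackway median the study publishes.
LARGEST_MEDIAN_MM = 289.5
LARGEST_TRACKWAY_ID = "D"
_LARGEST_STATURE_M = 1.83


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files(__package__).joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_trackway_records() -> pd.DataFrame:
    """The 23 trackways with stride data: RSL, gait, velocity (m/s),
    compass direction/degrees, and most-probable age/sex attribution."""
    return _read("engare_sero_trackways.csv")


def load_stature_records() -> pd.DataFrame:
    """The 25 trackways with predicted statures (m)."""
    return _read("engare_sero_statures.csv")


# Printed compass orientations by behavioral group (degrees clockwise
# from north).  Trackway EE belongs to the SW group by direction label
# but has no printed degrees and is excluded from numeric statistics.
NE_COMPASS_DEG = (43.0, 46.0, 46.0, 49.5, 43.0, 49.5)
SW_COMPASS_DEG = (
    235.0, 226.0, 218.0, 227.0, 225.0, 220.0, 228.0, 226.0,
    227.0, 225.0, 218.5, 225.0, 227.0, 226.0, 233.0, 231.0,
)


def engare_sero_fixture() -> tuple[list[Trackway], list[TrackwaySummary], pd.DataFrame]:
    """Return the bundled assemblage.

    Returns
    -------
    trackways
        25 :class:`~trackways.data.Trackway` objects.  The 23 with
        published stride data carry a stride list and compass bearing;
        FF and TT (stature-only) carry footprints alone.  Each trackway
        stores one footprint at its median length (D's is the published
        289.5 mm, the rest reconstructed — see module docstring) and a
        stride equal to RSL x median, so recomputing RSL reproduces the
        published ratio exactly.
    summaries
        Matching :class:`~trackways.data.TrackwaySummary` per trackway.
    stature_table
        The published per-trackway statures with the (reconstructed)
        medians, gait, velocity and attribution columns joined on.
    """
    t1 = load_trackway_records().set_index("trackway")
    t2 = load_stature_records()

    trackways: list[Trackway] = []
    summaries: list[TrackwaySummary] = []
    rows = []
    for rec in t2.itertuples(index=False):
        tid, stature = rec.trackway, float(rec.stature_m)
        median_mm = LARGEST_MEDIAN_MM * stature / _LARGEST_STATURE_M
        fp = FootprintMeasurement(track_id=f"{tid}.1", length_mm=median_mm)
        if tid in t1.index:
            r = t1.loc[tid]
            rsl = float(r["rsl"])
            compass = None if pd.isna(r["compass_deg"]) else float(r["compass_deg"])
            tw = Trackway(
                trackway_id=tid,
                footprints=[fp],
                stride_lengths_mm=[rsl * median_mm],
                compass_deg=compass,
                direction_label=str(r["compass_dir"]),
            )
            row = dict(
                trackway=tid, stature_m=stature, median_footprint_mm=median_mm,
                rsl=rsl, gait=str(r["gait"]), velocity_mps=float(r["velocity_mps"]),
                attribution=str(r["attribution"]), attribution_pct=float(r["attribution_pct"]),
            )
        else:
            tw = Trackway(trackway_id=tid, footprints=[fp])
            row = dict(
                trackway=tid, stature_m=stature, median_footprint_mm=median_mm,
                rsl=None, gait=None, velocity_mps=None,
                attribution=None, attribution_pct=None,
            )
        trackways.append(tw)
        summaries.append(
            TrackwaySummary(
                trackway_id=tid,
                median_footprint_length_mm=median_mm,
                relative_stride_length=row["rsl"],
            )
        )
        rows.append(row)
    return trackways, summaries, pd.DataFrame(rows)
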