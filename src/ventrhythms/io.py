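"""CSV interchange for series tables and point annotations.

Series tables carry an ISO-8601 UTC ``timestamp`` column plus one
column per variable; an empty cell is a missing observation. Point
tables carry ``frame_id, taxon, x, y`` rows in pixel coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series_prep import HourlySeries
from .spatial import LabelledPointSet

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_points_csv",
    "read_points_csv",
]


def write_series_csv(series: dict[str, HourlySeries] | HourlySeries, path) -> None:
    if isinstance(series, HourlySeries):
        series = {series.name or "value": series}
    frames = {name: s.to_series() for name, s in series.items()}
    df = pd.DataFrame(frames)
    df.index.name = "timestamp"
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")


def read_series_csv(path) -> dict[str, HourlySeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    idx = pd.DatetimeIndex(df.index)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    return {
        col: HourlySeries(idx, df[col].to_numpy(dtype=float), name=col)
        for col in df.columns
    }


def write_points_csv(points: LabelledPointSet, path) -> None:
    points.points.to_csv(path, index=False)


def read_points_csv(path, frame_width: int, frame_height: int,
                    pixel_area_cm2: float = 1.0) -> LabelledPointSet:
    df = pd.read_csv(path)
    return LabelledPointSet(
        df, frame_width=frame_width, frame_height=frame_height,
        pixel_area_cm2=pixel_area_cm2,
    )
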