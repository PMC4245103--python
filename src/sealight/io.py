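"""Reading and writing tag records, gridded rasters, and grid/track matching.

Tag files are UTF-8 delimited text with one header line
(``time,depth_m,light_level,temp_c,wet``) and ISO-8601 UTC timestamps.
Rasters are regular lat/lon grids carried in NetCDF (written through
xarray's scipy backend) with ``lat``/``lon`` cell-centre coordinates and
``units``/``time_start``/``n_days`` attributes; NaN is the missing-value
sentinel.  Satellite composite windows are 8-day periods anchored at
1 January of each year, with the final window of the year truncated.
Grid-cell membership is half-open, ``[edge, edge + step)``, on both axes.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["time", "depth_m", "light_level", "temp_c", "wet"]

LIGHT_LEVEL_RANGE = (0.0, 250.0)
MIN_RAW_DEPTH = -6.0  # m; pressure sensors may read slightly negative pre-correction


@dataclass
class Deployment:
    """One tag deployment: per-sample time, depth, light, temperature, wet flag.

    Arrays are parallel; ``time`` is ``datetime64[ns]`` UTC at a nominal 30-s
    cadence, ``depth`` is metres positive down.
    """

    seal_id: str
    time: np.ndarray
    depth: np.ndarray
    light_level: np.ndarray
    temperature: np.ndarray
    wet: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.depth = np.asarray(self.depth, dtype=float)
        self.light_level = np.asarray(self.light_level, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.wet = np.asarray(self.wet, dtype=bool)
        n = len(self.time)
        for name in ("depth", "light_level", "temperature", "wet"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length differs from time")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "depth_m": self.depth,
                "light_level": self.light_level,
                "temp_c": self.temperature,
                "wet": self.wet,
            }
        )

    @classmethod
    def from_frame(cls, seal_id: str, frame: pd.DataFrame) -> "Deployment":
        return cls(
            seal_id=seal_id,
            time=frame["time"].to_numpy(),
            depth=frame["depth_m"].to_numpy(),
            light_level=frame["light_level"].to_numpy(),
            temperature=frame["temp_c"].to_numpy(),
            wet=frame["wet"].to_numpy(),
        )


def write_tag_file(path: str | Path, deployment: Deployment) -> None:
    """Write a deployment in the tag text dialect (header + ISO-8601 times)."""
    frame = deployment.to_frame()
    frame["time"] = frame["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False)


def read_tag_file(path: str | Path, seal_id: str | None = None) -> Deployment:
    """Parse a tag file; rows violating record invariants are dropped.

    Columns are located by header name, so column order is free.  A missing
    mandatory column raises :class:`ValueError` naming the column.  Rows with
    a non-increasing timestamp, a light level outside [0, 250], or a depth
    below -6 m are dropped, and the total dropped count is logged.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in TAG_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"tag file {path} is missing mandatory column {col!r}")
    if seal_id is None:
        seal_id = path.stem
    if len(frame) == 0:
        empty = np.array([], dtype=float)
        return Deployment(seal_id, np.array([], dtype="datetime64[ns]"),
                          empty, empty, empty, np.array([], dtype=bool))
    frame["time"] = pd.to_datetime(frame["time"])
    lo, hi = LIGHT_LEVEL_RANGE
    valid = (
        frame["light_level"].between(lo, hi)
        & (frame["depth_m"] >= MIN_RAW_DEPTH)
        & frame["time"].notna()
    ).to_numpy()
    # strictly increasing times: greedily keep rows later than the last kept row
    times = frame["time"].to_numpy()
    last = None
    for i in range(len(frame)):
        if not valid[i]:
            continue
        if last is not None and times[i] <= last:
            valid[i] = False
            continue
        last = times[i]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("read_tag_file(%s): dropped %d invalid rows", path, n_dropped)
    return Deployment.from_frame(seal_id, frame[valid].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Rasters


@dataclass
class Raster:
    """Regular lat/lon grid of values with units and an optional time window.

    ``lat``/``lon`` are cell-centre coordinates with constant spacing;
    ``values`` has shape ``(len(lat), len(lon))`` and NaN marks missing
    cells.  ``time_start``/``n_days`` delimit the half-open composite window
    ``[time_start, time_start + n_days)``.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    units: str = ""
    time_start: dt.date | None = None
    n_days: int | None = None
    name: str = "values"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape does not match coordinates")
        for ax in (self.lat, self.lon):
            if len(ax) > 1:
                steps = np.diff(ax)
                if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                    raise ValueError("coordinate spacing must be constant")

    @property
    def lat_step(self) -> float:
        return float(self.lat[1] - self.lat[0]) if len(self.lat) > 1 else 1.0

    @property
    def lon_step(self) -> float:
        return float(self.lon[1] - self.lon[0]) if len(self.lon) > 1 else 1.0

    def contains(self, date: dt.date) -> bool:
        if self.time_start is None or self.n_days is None:
            return True
        delta = (date - self.time_start).days
        return 0 <= delta < self.n_days

    def cell_index(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Half-open cell membership: ``[edge, edge + step)`` on both axes."""
        i = int(np.floor((lat - (self.lat[0] - self.lat_step / 2)) / self.lat_step))
        j = int(np.floor((lon - (self.lon[0] - self.lon_step / 2)) / self.lon_step))
        if 0 <= i < len(self.lat) and 0 <= j < len(self.lon):
            return i, j
        return None

    def value_at(self, lat: float, lon: float) -> float:
        idx = self.cell_index(lat, lon)
        if idx is None:
            return float("nan")
        return float(self.values[idx])

    def box_values(self, lat_min: float, lat_max: float,
                   lon_min: float, lon_max: float) -> np.ndarray:
        """Values of all cells whose centres fall in the half-open box."""
        li = (self.lat >= lat_min) & (self.lat < lat_max)
        lj = (self.lon >= lon_min) & (self.lon < lon_max)
        return self.values[np.ix_(li, lj)]

    def to_xarray(self) -> xr.DataArray:
        attrs = {"units": self.units}
        if self.time_start is not None:
            attrs["time_start"] = self.time_start.isoformat()
            attrs["n_days"] = int(self.n_days)
        return xr.DataArray(
            self.values, dims=("lat", "lon"),
            coords={"lat": self.lat, "lon": self.lon},
            attrs=attrs, name=self.name,
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "Raster":
        with xr.open_dataset(path, engine="scipy") as ds:
            name = list(ds.data_vars)[0]
            da = ds[name].load()
        time_start = da.attrs.get("time_start")
        return cls(
            values=da.values,
            lat=da["lat"].values,
            lon=da["lon"].values,
            units=str(da.attrs.get("units", "")),
            time_start=dt.date.fromisoformat(time_start) if time_start else None,
            n_days=int(da.attrs["n_days"]) if "n_days" in da.attrs else None,
            name=name,
        )


def match_grid(position: tuple[float, float], date: dt.date,
               grids: list[Raster]) -> float:
    """Value of the cell containing ``position`` from the grid whose 8-day
    window contains ``date``; NaN when the cell is masked or no window covers
    the date."""
    lat, lon = position
    for grid in grids:
        if grid.contains(date):
            return grid.value_at(lat, lon)
    return float("nan")


def window_start_of(date: dt.date, window_days: int = 8) -> dt.date:
    """Start date of the composite window containing ``date`` (anchored Jan 1)."""
    doy = (date - dt.date(date.year, 1, 1)).days
    return dt.date(date.year, 1, 1) + dt.timedelta(days=(doy // window_days) * window_days)


def eight_day_windows(start: dt.date, end: dt.date,
                      window_days: int = 8) -> list[tuple[dt.date, int]]:
    """(window_start, length) pairs covering ``[start, end)``; windows are
    anchored at Jan 1 of each year, the final window of a year truncated."""
    windows: list[tuple[dt.date, int]] = []
    cur = window_start_of(start, window_days)
    while cur < end:
        year_end = dt.date(cur.year + 1, 1, 1)
        length = min(window_days, (year_end - cur).days)
        windows.append((cur, length))
        cur = cur + dt.timedelta(days=length)
    return windows
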