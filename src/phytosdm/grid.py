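"""Monthly 1-degree grid conventions shared by every stage of the pipeline.

Cells are half-open 1-degree boxes ``[lat, lat+1) x [lon, lon+1)``; a record at
coordinate ``(lat, lon)`` belongs to the cell given by ``floor`` of its
coordinates, and cell centers sit at ``edge + 0.5``.  Climatologies are stored
as :class:`xarray.Dataset` objects with dimensions ``(month, lat, lon)`` —
``month`` is always the twelve calendar months — plus optional static 2-D
fields such as bathymetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

MONTHS = tuple(range(1, 13))

#: Variables that do not vary with month (dimension (lat, lon) only).
STATIC_VARS = ("bathymetry",)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a monthly 1-degree grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of latitude / longitude cells (each cell spans one degree).
    lat_min, lon_min
        Southern / western edge of the grid in degrees.
    """

    n_lat: int
    n_lon: int
    lat_min: float = -30.0
    lon_min: float = 0.0
    months: tuple = field(default=MONTHS)

    def __post_init__(self):
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid needs at least 2x2 cells")
        if tuple(self.months) != MONTHS:
            raise ValueError("months must be the 12 calendar months 1..12")
        if self.lat_min < -90 or self.lat_min + self.n_lat > 90:
            raise ValueError("latitude extent outside [-90, 90]")

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + 0.5 + np.arange(self.n_lat)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + 0.5 + np.arange(self.n_lon)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon

    def cell_index(self, lat, lon):
        """Map coordinates to ``(lat_idx, lon_idx)``; -1 where off-grid.

        Uses the half-open floor convention, so e.g. lat == lat_min maps to
        row 0 and lat == lat_max falls off the grid.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        li = np.floor(lat - self.lat_min).astype(int)
        lj = np.floor(lon - self.lon_min).astype(int)
        bad = (li < 0) | (li >= self.n_lat) | (lj < 0) | (lj >= self.n_lon)
        bad |= ~np.isfinite(lat) | ~np.isfinite(lon)
        li = np.where(bad, -1, li)
        lj = np.where(bad, -1, lj)
        return li, lj


def grid_of(env: xr.Dataset) -> GridSpec:
    """Recover the :class:`GridSpec` of a climatology dataset."""
    lat = env["lat"].values
    lon = env["lon"].values
    return GridSpec(
        n_lat=lat.size,
        n_lon=lon.size,
        lat_min=float(lat[0] - 0.5),
        lon_min=float(lon[0] - 0.5),
    )


def empty_climatology(spec: GridSpec) -> xr.Dataset:
    return xr.Dataset(
        coords={
            "month": np.array(MONTHS, dtype=int),
            "lat": spec.lat_centers,
            "lon": spec.lon_centers,
        }
    )


def field_at(
    env: xr.Dataset, var: str, month, lat_idx, lon_idx
) -> np.ndarray:
    """Vectorized lookup of a climatology variable at monthly cells.

    ``month`` is ignored for static variables.  Out-of-range indices return
    NaN rather than raising.
    """
    da = env[var]
    vals = da.values
    lat_idx = np.asarray(lat_idx, dtype=int)
    lon_idx = np.asarray(lon_idx, dtype=int)
    ok = (
        (lat_idx >= 0)
        & (lat_idx < env.sizes["lat"])
        & (lon_idx >= 0)
        & (lon_idx < env.sizes["lon"])
    )
    out = np.full(lat_idx.shape, np.nan)
    if "month" in da.dims:
        month = np.asarray(month, dtype=int)
        ok = ok & (month >= 1) & (month <= 12)
        out[ok] = vals[month[ok] - 1, lat_idx[ok], lon_idx[ok]]
    else:
        out[ok] = vals[lat_idx[ok], lon_idx[ok]]
    return out


def write_climatology(env: xr.Dataset, path) -> None:
    """Write a climatology to NetCDF (``.nc``) or long-format CSV."""
    path = str(path)
    if path.endswith(".csv"):
        climatology_to_frame(env).to_csv(path, index=False)
    else:
        env.to_netcdf(path, engine="scipy")


def read_climatology(path) -> xr.Dataset:
    path = str(path)
    if path.endswith(".csv"):
        return frame_to_climatology(pd.read_csv(path))
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def climatology_to_frame(env: xr.Dataset) -> pd.DataFrame:
    """Long-format view: one row per (variable, month, lat, lon) value."""
    frames = []
    for var in env.data_vars:
        da = env[var]
        df = da.to_dataframe(name="value").reset_index()
        if "month" not in df.columns:
            df["month"] = 0  # static field marker
        df["variable"] = var
        frames.append(df[["variable", "month", "lat", "lon", "value"]])
    return pd.concat(frames, ignore_index=True)


def frame_to_climatology(df: pd.DataFrame) -> xr.Dataset:
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    out = xr.Dataset(
        coords={"month": np.array(MONTHS, dtype=int), "lat": lats, "lon": lons}
    )
    for var, sub in df.groupby("variable"):
        static = (sub["month"] == 0).all()
        if static:
            piv = sub.pivot_table(index="lat", columns="lon", values="value")
            piv = piv.reindex(index=lats, columns=lons)
            out[var] = (("lat", "lon"), piv.values)
        else:
            arr = np.full((12, lats.size, lons.size), np.nan)
            li = np.searchsorted(lats, sub["lat"].values)
            lj = np.searchsorted(lons, sub["lon"].values)
            arr[sub["month"].values - 1, li, lj] = sub["value"].values
            out[var] = (("month", "lat", "lon"), arr)
    return out
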