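"""Occurrence cleaning, open-ocean masking, monthly 1-degree binning, thinning.

The exclusion rules are applied in a fixed order and every dropped row is
attributed to exactly one (first-failing) rule, so the :class:`FilterReport`
counts always sum back to the input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, field_at, grid_of

EARTH_RADIUS_KM = 6371.0


@dataclass
class FilterReport:
    """Per-rule removal counts; ``removed + retained == input``."""

    input_rows: int = 0
    retained: int = 0
    removed: dict = field(default_factory=dict)

    def check(self) -> bool:
        return self.input_rows == self.retained + sum(self.removed.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_rows": self.input_rows,
                "retained": self.retained,
                "removed": self.removed,
            },
            indent=2,
        )


def normalize_longitudes(lon):
    """Map longitudes from [-360, 360] into [-180, 180)."""
    lon = np.asarray(lon, dtype=float)
    return (lon + 180.0) % 360.0 - 180.0


def filter_records(
    records: pd.DataFrame,
    env: xr.Dataset,
    year_range: tuple = (1800, 2015),
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the record-quality exclusion rules in order.

    Rules (first failure wins): (1) basis listed as fossil or preserved
    specimen; (2) collection year outside ``year_range``; (3) negative depth;
    (4) nonsensible coordinates (|lat| > 90, lon outside [-360, 360], or
    non-numeric); (5) depth below the monthly climatological mixed layer at
    the record's cell.  Rows without a depth are kept whenever their species
    has at least one retained record inside the mixed layer (the mixed-layer
    species assumption); otherwise they are counted separately.  Rows needing
    the MLD rule but lacking a month (or falling off-grid) are flagged and
    excluded under their own counter.

    Longitudes of retained rows are normalized to [-180, 180).
    """
    rec = records.copy().reset_index(drop=True)
    n = len(rec)
    report = FilterReport(input_rows=n)
    removed_rule = np.full(n, "", dtype=object)
    alive = np.ones(n, dtype=bool)

    basis = rec["basis"].astype(str).str.lower()
    bad = alive & basis.isin(["fossil specimen", "preserved specimen"]).values
    removed_rule[bad] = "fossil_or_preserved"
    alive &= ~bad

    year = pd.to_numeric(rec["year"], errors="coerce")
    bad = alive & (~np.isfinite(year) | (year < year_range[0]) | (year > year_range[1])).values
    removed_rule[bad] = "year_out_of_range"
    alive &= ~bad

    depth = pd.to_numeric(rec["depth"], errors="coerce").values
    bad = alive & np.isfinite(depth) & (depth < 0)
    removed_rule[bad] = "negative_depth"
    alive &= ~bad

    lat = pd.to_numeric(rec["lat"], errors="coerce").values
    lon = pd.to_numeric(rec["lon"], errors="coerce").values
    bad = alive & (
        ~np.isfinite(lat)
        | ~np.isfinite(lon)
        | (np.abs(lat) > 90)
        | (np.abs(lon) > 360)
    )
    removed_rule[bad] = "nonsensible_coordinates"
    alive &= ~bad
    lon = normalize_longitudes(lon)
    rec["lon"] = lon

    # mixed-layer rule, exact month
    spec = grid_of(env)
    li, lj = spec.cell_index(lat, lon)
    month = pd.to_numeric(rec["month"], errors="coerce").values
    has_depth = np.isfinite(depth)
    month_ok = np.isfinite(month) & (month >= 1) & (month <= 12)
    mld = np.full(n, np.nan)
    idx = alive & month_ok & (li >= 0)
    mld[idx] = field_at(
        env, "MLD", month[idx].astype(int), li[idx], lj[idx]
    )

    needs_mld = alive & has_depth
    no_month = needs_mld & ~(month_ok & np.isfinite(mld))
    removed_rule[no_month] = "mld_undeterminable"
    alive &= ~no_month

    below = alive & has_depth & (depth > mld)
    removed_rule[below] = "below_mixed_layer"
    alive &= ~below

    # species recorded at least once within the mixed layer qualify
    in_ml = alive & has_depth & (depth <= mld)
    ml_species = set(rec.loc[in_ml, "species_id"])
    missing_depth = alive & ~has_depth
    unqualified = missing_depth & ~rec["species_id"].isin(ml_species).values
    removed_rule[unqualified] = "missing_depth_not_mixed_layer_species"
    alive &= ~unqualified

    for rule in [
        "fossil_or_preserved",
        "year_out_of_range",
        "negative_depth",
        "nonsensible_coordinates",
        "mld_undeterminable",
        "below_mixed_layer",
        "missing_depth_not_mixed_layer_species",
    ]:
        report.removed[rule] = int((removed_rule == rule).sum())
    report.retained = int(alive.sum())
    assert report.check()
    return rec.loc[alive].reset_index(drop=True), report


def apply_open_ocean_mask(
    records: pd.DataFrame,
    env: xr.Dataset,
    min_bathymetry: float = 200.0,
    min_salinity: float = 20.0,
    drop_missing_bathymetry: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop records from shelf seas (< 200 m deep) or brackish water (S < 20).

    Salinity is checked at the record's month where available, else the
    annual mean.  Cells with missing bathymetry are excluded (and counted)
    by default.
    """
    rec = records.reset_index(drop=True)
    n = len(rec)
    report = FilterReport(input_rows=n)
    spec = grid_of(env)
    li, lj = spec.cell_index(rec["lat"].values, rec["lon"].values)
    month = pd.to_numeric(rec["month"], errors="coerce").fillna(1).astype(int).values
    month = np.clip(month, 1, 12)

    bathy = field_at(env, "bathymetry", month, li, lj)
    sal = field_at(env, "S", month, li, lj)

    alive = np.ones(n, dtype=bool)
    rule = np.full(n, "", dtype=object)

    bad = alive & ~np.isfinite(bathy)
    if drop_missing_bathymetry:
        rule[bad] = "missing_bathymetry"
        alive &= ~bad

    bad = alive & np.isfinite(bathy) & (bathy < min_bathymetry)
    rule[bad] = "shallow_sea"
    alive &= ~bad

    bad = alive & np.isfinite(sal) & (sal < min_salinity)
    rule[bad] = "low_salinity"
    alive &= ~bad

    for r in ["missing_bathymetry", "shallow_sea", "low_salinity"]:
        report.removed[r] = int((rule == r).sum())
    report.retained = int(alive.sum())
    assert report.check()
    return rec.loc[alive].reset_index(drop=True), report


@dataclass
class GriddedPresences:
    """Unique (species, month, cell) presences after monthly 1-degree binning."""

    table: pd.DataFrame  # columns species_id, month, lat_idx, lon_idx

    @property
    def counts(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=int, name="presences")
        return (
            self.table.groupby("species_id").size().rename("presences")
        )

    def for_species(self, species_id) -> pd.DataFrame:
        return self.table[self.table["species_id"] == species_id]


def bin_presences(records: pd.DataFrame, spec: GridSpec) -> GriddedPresences:
    """Collapse records to one presence per unique (species, month, cell).

    Rows from different years in the same monthly cell count once.  Records
    falling off the grid or without a month are ignored.
    """
    if records.empty:
        return GriddedPresences(
            pd.DataFrame(columns=["species_id", "month", "lat_idx", "lon_idx"])
        )
    li, lj = spec.cell_index(records["lat"].values, records["lon"].values)
    month = pd.to_numeric(records["month"], errors="coerce").values
    ok = (li >= 0) & np.isfinite(month) & (month >= 1) & (month <= 12)
    tab = pd.DataFrame(
        {
            "species_id": records["species_id"].values[ok],
            "month": month[ok].astype(int),
            "lat_idx": li[ok],
            "lon_idx": lj[ok],
        }
    ).drop_duplicates(ignore_index=True)
    tab = tab.sort_values(list(tab.columns), ignore_index=True)
    return GriddedPresences(tab)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_presences(
    records: pd.DataFrame,
    min_km: float,
    seed: int = 0,
    shuffle: bool = False,
) -> pd.DataFrame:
    """Greedy per-species spatial thinning to a minimum pairwise distance.

    Records of each species are scanned first-come (input order by default;
    seeded shuffling when ``shuffle=True``) and kept only if at least
    ``min_km`` from every record of that species already kept.
    """
    if min_km <= 0:
        raise ValueError("min_km must be > 0")
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, sub in records.groupby("species_id", sort=False):
        order = sub.index.to_numpy()
        if shuffle:
            order = rng.permutation(order)
        kept_lat, kept_lon, kept = [], [], []
        for i in order:
            la, lo = records.at[i, "lat"], records.at[i, "lon"]
            if kept:
                d = haversine_km(
                    np.array(kept_lat), np.array(kept_lon), la, lo
                )
                if (d < min_km).any():
                    continue
            kept.append(i)
            kept_lat.append(la)
            kept_lon.append(lo)
        keep_idx.extend(kept)
    return records.loc[sorted(keep_idx)].reset_index(drop=True)


def apply_synonym_map(records: pd.DataFrame, synonyms: dict) -> pd.DataFrame:
    """Replace species ids by a user-supplied synonym map, verbatim."""
    out = records.copy()
    out["species_id"] = out["species_id"].map(lambda s: synonyms.get(s, s))
    return out
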