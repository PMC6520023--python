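"""Target-group pseudoabsence sampling with T x MLD stratification.

Presence-only data carry the survey effort of whoever collected them; drawing
background ("pseudoabsence") cells from the pooled presences of a broad
target group hands the same spatial and seasonal bias to the absences, so the
model fits the niche rather than the sampling pattern.  Background totals are
ten background cells per presence, apportioned over 81 equal-width
temperature x mixed-layer-depth strata proportionally to how many monthly
1-degree target-group cells each stratum holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import field_at
from .prep import GriddedPresences

#: Taxa large enough in the source data to act as their own target group.
GROUP_SPECIFIC_TAXA = ("Bacillariophyceae", "Dinoflagellata", "Haptophyta")

#: Taxon whose strongly imbalanced sampling excludes it from the shared pool.
IMBALANCED_TAXON = "Bacillariophyceae"


@dataclass
class TargetGroup:
    """Pooled monthly 1-degree presence cells of a group of species."""

    species_ids: tuple
    cells: pd.DataFrame  # month, lat_idx, lon_idx, multiplicity

    def __post_init__(self):
        if self.cells.empty:
            raise ValueError("target group has no cells")


def _pool_cells(table: pd.DataFrame) -> pd.DataFrame:
    out = (
        table.groupby(["month", "lat_idx", "lon_idx"])
        .size()
        .rename("multiplicity")
        .reset_index()
    )
    return out


def build_target_group(
    presences: GriddedPresences,
    group_map: dict,
    mode: str = "group-specific",
) -> dict:
    """Assign a :class:`TargetGroup` to every species.

    ``group_map`` maps species_id -> taxon label.  In ``group-specific``
    mode, species of the taxa in :data:`GROUP_SPECIFIC_TAXA` draw from their
    own taxon's pooled cells; every other species draws from the pool of all
    species excluding the north-south-imbalanced taxon.  In ``total`` mode
    all species share the all-species pool.
    """
    if mode not in ("group-specific", "total"):
        raise ValueError("mode must be 'group-specific' or 'total'")
    tab = presences.table
    missing = [s for s in tab["species_id"].unique() if s not in group_map]
    if missing and mode == "group-specific":
        warnings.warn(
            f"{len(missing)} species with unknown taxon fall back to the total pool"
        )
    taxon = tab["species_id"].map(lambda s: group_map.get(s))

    all_species = tuple(sorted(tab["species_id"].unique()))
    total_pool = TargetGroup(all_species, _pool_cells(tab))
    out = {}
    if mode == "total":
        return {s: total_pool for s in all_species}

    pools = {}
    for t in GROUP_SPECIFIC_TAXA:
        sub = tab[taxon == t]
        if not sub.empty:
            pools[t] = TargetGroup(
                tuple(sorted(sub["species_id"].unique())), _pool_cells(sub)
            )
    rest = tab[taxon != IMBALANCED_TAXON]
    rest_pool = (
        TargetGroup(tuple(sorted(rest["species_id"].unique())), _pool_cells(rest))
        if not rest.empty
        else total_pool
    )
    for s in all_species:
        t = group_map.get(s)
        if t in pools:
            out[s] = pools[t]
        elif t is None:
            out[s] = total_pool
        else:
            out[s] = rest_pool
    return out


def _cell_key(month, lat_idx, lon_idx):
    return (
        np.asarray(month, np.int64) * 10_000_000_000
        + (np.asarray(lat_idx, np.int64) + 1000) * 1_000_000
        + np.asarray(lon_idx, np.int64)
        + 1000
    )


@dataclass
class StratumAssignment:
    """Stratum membership of every usable target-group cell."""

    cells: pd.DataFrame  # month, lat_idx, lon_idx, multiplicity, T, MLD, stratum
    t_edges: np.ndarray
    mld_edges: np.ndarray
    n_dropped_missing: int = 0

    @property
    def n_strata(self) -> int:
        return (len(self.t_edges) - 1) * (len(self.mld_edges) - 1)

    def __post_init__(self):
        # per-stratum row indices, computed once; reused for every species
        strat = self.cells["stratum"].to_numpy()
        order = np.argsort(strat, kind="stable")
        sids, starts = np.unique(strat[order], return_index=True)
        bounds = np.append(starts, strat.size)
        self.stratum_ids = sids
        self.stratum_rows = {
            sid: order[bounds[i]: bounds[i + 1]] for i, sid in enumerate(sids)
        }
        self.cell_keys = _cell_key(
            self.cells["month"], self.cells["lat_idx"], self.cells["lon_idx"]
        )


def _bin_axis(values: np.ndarray, n_bins: int, name: str):
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        warnings.warn(f"degenerate {name} span; using a single bin")
        return np.array([lo, hi]), np.zeros(values.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    return edges, idx  # max edge inclusive via the clip


def stratify(
    group: TargetGroup, env: xr.Dataset, n_bins: int = 9
) -> StratumAssignment:
    """Split the group's cells into ``n_bins**2`` equal-width T x MLD strata.

    Bin edges span the min..max of T and MLD over the group's own monthly
    cells, with the maximum edge inclusive; cells where either field is
    missing are dropped and counted.
    """
    cells = group.cells.copy()
    T = field_at(env, "T", cells["month"].values, cells["lat_idx"].values,
                 cells["lon_idx"].values)
    MLD = field_at(env, "MLD", cells["month"].values, cells["lat_idx"].values,
                   cells["lon_idx"].values)
    ok = np.isfinite(T) & np.isfinite(MLD)
    dropped = int((~ok).sum())
    cells = cells.loc[ok].reset_index(drop=True)
    T, MLD = T[ok], MLD[ok]
    if cells.empty:
        raise ValueError("no target-group cells with T and MLD defined")
    t_edges, ti = _bin_axis(T, n_bins, "T")
    m_edges, mi = _bin_axis(MLD, n_bins, "MLD")
    n_mld = len(m_edges) - 1
    cells["T"] = T
    cells["MLD"] = MLD
    cells["t_bin"] = ti + 1
    cells["mld_bin"] = mi + 1
    cells["stratum"] = ti * n_mld + mi + 1
    return StratumAssignment(cells, t_edges, m_edges, dropped)


@dataclass
class BackgroundSet:
    species_id: str
    table: pd.DataFrame  # month, lat_idx, lon_idx, stratum
    target_size: int

    @property
    def realized_size(self) -> int:
        return len(self.table)


def largest_remainder_quotas(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` into integer quotas proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or total <= 0:
        return np.zeros(weights.size, dtype=int)
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def sample_background(
    species_id: str,
    presences: GriddedPresences,
    group: TargetGroup,
    strata: StratumAssignment,
    ratio: int = 10,
    seed: int = 0,
) -> BackgroundSet:
    """Draw ``ratio`` background cells per presence of ``species_id``.

    Stratum quotas are proportional to the number of monthly target-group
    cells per stratum (largest-remainder rounding conserves the total);
    within a stratum, cells are drawn uniformly without replacement.  The
    species' own presence cells are never drawn.  If a stratum runs out of
    eligible cells, its deficit is redistributed proportionally over strata
    that still have spare cells; if the whole pool runs out, all available
    cells are returned with a warning.
    """
    own = presences.for_species(species_id)
    n_pres = len(own)
    if n_pres == 0:
        raise ValueError(f"species {species_id} has no presences")
    target = ratio * n_pres

    pool = strata.cells
    own_keys = _cell_key(own["month"], own["lat_idx"], own["lon_idx"])
    eligible = ~np.isin(strata.cell_keys, own_keys)

    sids = strata.stratum_ids
    count_all = np.array([strata.stratum_rows[s].size for s in sids])
    avail = np.array(
        [int(eligible[strata.stratum_rows[s]].sum()) for s in sids]
    )
    quotas = largest_remainder_quotas(count_all, target)

    # redistribute deficits of exhausted strata
    for _ in range(len(sids)):
        deficit = np.maximum(quotas - avail, 0)
        if deficit.sum() == 0:
            break
        quotas = np.minimum(quotas, avail)
        spare = avail - quotas
        extra = largest_remainder_quotas(spare, int(min(deficit.sum(), spare.sum())))
        quotas = quotas + extra
    quotas = np.minimum(quotas, avail)
    if quotas.sum() < target:
        warnings.warn(
            f"{species_id}: only {quotas.sum()} of {target} background cells available"
        )

    rng = np.random.default_rng(seed)
    picks = []
    for sid, q in zip(sids, quotas):
        if q == 0:
            continue
        rows = strata.stratum_rows[sid]
        rows = rows[eligible[rows]]
        take = rng.choice(rows.size, size=int(q), replace=False)
        picks.append(rows[np.sort(take)])
    if picks:
        table = pool.iloc[np.concatenate(picks)][
            ["month", "lat_idx", "lon_idx", "stratum"]
        ].reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=["month", "lat_idx", "lon_idx", "stratum"])
    return BackgroundSet(species_id, table, target)
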