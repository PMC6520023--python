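"""Virtual-species world: environmental climatologies, niches, biased sampling.

The simulator produces the three ingredients the rest of the pipeline consumes,
with known ground truth:

* monthly gridded environmental fields with the statistical structure of an
  ocean climatology (poleward temperature decline, mid-latitude seasonality,
  nutrient-temperature anticorrelation, winter-deep mixed layers);
* species pools with unimodal (Gaussian) environmental niches, including pools
  whose overlapping thermal ranges follow the metabolic-theory expectation
  ``ln S = c - E/(kT)``;
* presence-only occurrence records drawn under strongly uneven spatial
  sampling effort, mimicking the heavy concentration of historical sampling
  in one ocean basin.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import constants
from scipy.ndimage import gaussian_filter

from .grid import MONTHS, GridSpec, empty_climatology

#: Boltzmann constant in eV per kelvin.
K_BOLTZMANN_EV = constants.value("Boltzmann constant in eV/K")

CELSIUS_OFFSET = 273.15


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentConfig:
    """Knobs of the synthetic climatology.

    ``t_range`` is the closed bound for sea-surface temperature; generated
    values are clipped into it (with a warning) if noise or seasonality would
    escape.  ``seasonal_amplitude`` is the maximal monthly temperature
    excursion, reached toward the poleward grid edge; the tropics get none.
    ``nutrient_coupling`` in [0, 1] sets how tightly nitrate mirrors (the
    inverse of) temperature.
    """

    t_range: tuple = (-1.8, 32.0)
    seasonal_amplitude: float = 3.0
    no3_max: float = 22.0
    nutrient_coupling: float = 0.85
    mld_base: float = 30.0
    mld_polar_extra: float = 150.0
    mld_seasonality: float = 0.7
    par_max: float = 50.0
    land_fraction: float = 0.05
    shelf_fraction: float = 0.05
    low_salinity_fraction: float = 0.01
    noise_sd: float = 0.6
    noise_smoothing: float = 1.5


def _smooth_noise(rng, shape, sigma):
    """Seeded spatially smooth noise field, unit variance, periodic in lon."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_environment(
    spec: GridSpec, config: EnvironmentConfig | None = None, seed: int = 0
) -> xr.Dataset:
    """Generate a 12-month synthetic climatology on ``spec``.

    Returns a dataset with variables T, S, NO3, PO4, SiOH4, MLD, PAR, Chl,
    wind, pCO2 (monthly) and bathymetry (static).  A common land mask (NaN)
    is applied to all monthly fields in every month.  Each seasonal field
    peaks in its own month (temperature in late local summer, mixing depth
    and wind in winter, nutrients and chlorophyll around the late-winter /
    spring recharge, light at the solstice), so the month-to-month tendency
    fields are not mutually collinear — mirroring the partial decoupling of
    real climatologies.
    """
    config = config or EnvironmentConfig()
    if not isinstance(spec, GridSpec):
        raise TypeError("spec must be a GridSpec")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = config.t_range
    if t_lo >= t_hi:
        raise ValueError("t_range must be increasing")

    lat = spec.lat_centers
    half_span = max(abs(spec.lat_min), abs(spec.lat_max))
    phi = np.clip(np.abs(lat) / half_span, 0.0, 1.0)  # 0 equator .. 1 edge
    months = np.array(MONTHS, dtype=float)

    shape = (spec.n_lat, spec.n_lon)
    noise = lambda scale=1.0: scale * _smooth_noise(  # noqa: E731
        rng, shape, config.noise_smoothing
    )

    def noise3d(scale=1.0):
        # spatially smooth but independent between months
        return scale * np.stack(
            [_smooth_noise(rng, shape, config.noise_smoothing) for _ in MONTHS]
        )

    def season(peak_north: float):
        """cos season peaking at ``peak_north`` (shifted 6 months south)."""
        peak = np.where(lat >= 0, peak_north, peak_north + 6.0)
        return np.cos(2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0)[
            :, :, None
        ]

    # --- temperature: warm equator, cold poleward edge, late-summer peak
    t_base = t_lo + (t_hi - t_lo) * np.cos(phi * np.pi / 2.0) ** 1.2
    amp = config.seasonal_amplitude * np.sin(phi * np.pi / 2.0)
    T = (
        t_base[None, :, None]
        + amp[None, :, None] * season(8.0)
        + noise(config.noise_sd)[None, :, :]
        + noise3d(0.2)
    )
    if T.min() < t_lo or T.max() > t_hi:
        warnings.warn("temperature pushed outside configured bounds; clipping")
        T = np.clip(T, t_lo, t_hi)

    t_rel = (t_hi - T) / (t_hi - t_lo)  # 0 warm .. 1 cold

    # --- nutrients: track monthly temperature (winter-mixing recharge)
    c = config.nutrient_coupling
    NO3 = config.no3_max * (
        c * t_rel ** 1.2 + (1 - c) * np.abs(noise(1.0))[None, :, :] * 0.5
    )
    # floors mimic analytical detection limits: no exact zeros in climatologies
    NO3 = np.clip(NO3 + noise3d(0.5), 0.01, None)
    PO4 = np.clip(NO3 / 16.0 + 0.04 * noise3d(1.0), 0.001, None)
    SiOH4 = np.clip(0.8 * NO3 + 1.5 * np.abs(noise3d(1.0)), 0.01, None)

    # --- mixed layer: cold water mixes deep (winter-deep via T's seasonality)
    MLD = (
        config.mld_base
        + config.mld_polar_extra * t_rel ** 1.7
        + config.mld_seasonality * 20.0 * phi[None, :, None] * season(2.0)
        + 8.0 * noise3d(1.0)
    )
    MLD = np.clip(MLD, 5.0, None)

    # --- light: bright warm surface waters, solstice modulation
    PAR = config.par_max * (
        1.0 - 0.85 * t_rel ** 1.2 + 0.12 * phi[None, :, None] * season(6.0)
    ) + noise3d(1.5)
    PAR = np.clip(PAR, 1.0, None)

    # --- chlorophyll: weakly nutrient-driven, spring-bloom peak, patchy
    Chl = np.clip(
        0.1
        + 0.008 * NO3 * (1.0 + 0.4 * season(4.0) * phi[None, :, None])
        + 0.15 * np.abs(noise3d(1.0)),
        0.01,
        None,
    )

    # --- wind: mid-latitude storm tracks, winter peak
    wind = np.clip(
        5.0
        + 5.0 * np.sin(np.clip(phi * np.pi, 0, np.pi))[None, :, None] ** 2
        + 1.2 * season(1.0)
        + noise3d(1.2),
        0.0,
        None,
    )
    pCO2 = 380.0 + 0.3 * (T - T.mean()) + 12.0 * noise3d(1.0)

    S = 35.0 + 1.2 * noise(1.0)[None, :, :] + 0.5 * t_rel + 0.4 * noise3d(1.0)
    # brackish patches (marginal-sea analogues) to exercise the salinity mask
    n_cells = spec.n_lat * spec.n_lon
    n_fresh = int(round(config.low_salinity_fraction * n_cells))
    if n_fresh:
        idx = rng.choice(n_cells, size=n_fresh, replace=False)
        S.reshape(12, -1)[:, idx] = rng.uniform(10.0, 19.5, size=n_fresh)

    bathy = np.clip(4000.0 + 600.0 * noise(1.0), 300.0, None)
    n_shelf = int(round(config.shelf_fraction * n_cells))
    if n_shelf:
        idx = rng.choice(n_cells, size=n_shelf, replace=False)
        bathy.reshape(-1)[idx] = rng.uniform(20.0, 190.0, size=n_shelf)

    land = _smooth_noise(rng, shape, config.noise_smoothing * 2)
    thresh = np.quantile(land, 1.0 - config.land_fraction)
    land_mask = land > thresh if config.land_fraction > 0 else np.zeros(shape, bool)

    env = empty_climatology(spec)
    monthly = {
        "T": T,
        "S": S,
        "NO3": NO3,
        "PO4": PO4,
        "SiOH4": SiOH4,
        "MLD": MLD,
        "PAR": PAR,
        "Chl": Chl,
        "wind": wind,
        "pCO2": pCO2,
    }
    for name, arr in monthly.items():
        arr = arr.copy()
        arr[:, land_mask] = np.nan
        env[name] = (("month", "lat", "lon"), arr)
    bathy = bathy.copy()
    bathy[land_mask] = np.nan
    env["bathymetry"] = (("lat", "lon"), bathy)
    env.attrs["land_fraction"] = config.land_fraction
    return env


# ---------------------------------------------------------------------------
# species pools
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTruth:
    """Ground-truth niche of one virtual species.

    ``niche`` maps an environmental variable name to a Gaussian response
    ``(optimum, breadth)``; overall suitability is the product across
    variables scaled by ``p_max`` (the occurrence probability at the niche
    center).  ``thermal_range`` is the hard presence range used by the
    metabolic pools to define range overlap.
    """

    species_id: str
    taxon: str
    niche: Mapping[str, tuple]
    p_max: float = 0.5
    thermal_range: tuple | None = None

    def __post_init__(self):
        for var, (opt, breadth) in self.niche.items():
            if breadth <= 0:
                raise ValueError(f"breadth must be > 0 for {var}")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")

    def suitability(self, env: xr.Dataset) -> xr.DataArray:
        """Occurrence probability per (month, lat, lon); in [0, p_max]."""
        out = None
        for var, (opt, breadth) in self.niche.items():
            g = np.exp(-0.5 * ((env[var] - opt) / breadth) ** 2)
            out = g if out is None else out * g
        return self.p_max * out


@dataclass
class NicheConfig:
    """Distributions of niche optima and breadths per predictor.

    ``optima`` / ``breadths`` map variable name -> (low, high) uniform
    sampling bounds.  ``p_max`` applies to every species.
    """

    optima: Mapping[str, tuple] = dc_field(
        default_factory=lambda: {"T": (0.0, 30.0)}
    )
    breadths: Mapping[str, tuple] = dc_field(
        default_factory=lambda: {"T": (3.0, 6.0)}
    )
    p_max: float = 0.5


def generate_species_pool(
    n_species: int, niche_config: NicheConfig | None = None, seed: int = 0
) -> list[SpeciesTruth]:
    """Draw ``n_species`` random unimodal niches."""
    cfg = niche_config or NicheConfig()
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    for var, (lo, hi) in cfg.breadths.items():
        if lo <= 0 or hi <= 0:
            raise ValueError(f"breadth bounds must be positive for {var}")
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_species):
        niche = {}
        for var in cfg.optima:
            opt = rng.uniform(*cfg.optima[var])
            breadth = rng.uniform(*cfg.breadths[var])
            niche[var] = (opt, breadth)
        pool.append(
            SpeciesTruth(
                species_id=f"sp{i:04d}", taxon="virtual", niche=niche,
                p_max=cfg.p_max,
            )
        )
    return pool


def generate_metabolic_pool(
    n_species: int,
    activation_energy: float,
    env: xr.Dataset,
    seed: int = 0,
    range_width: float = 10.0,
    p_max: float = 0.5,
    secondary_vars: tuple = (),
    secondary_breadth_scale: float = 2.0,
) -> tuple[list[SpeciesTruth], float]:
    """Pool whose overlapping thermal ranges follow ``ln S = c - E/(kT)``.

    Species get fixed-width thermal ranges (width ``range_width`` deg C) whose
    midpoints are drawn with density proportional to ``exp(-E/(kT))`` (T in
    kelvin).  The count of ranges covering a temperature T is then
    ``n * integral of the density over T +/- w/2``, i.e. log-linear in 1/kT up
    to a smoothing factor that is nearly constant over the ocean's span.
    Midpoints are drawn on the grid's T span padded by half a range width so
    the overlap count has no edge droop inside the span.

    Besides the dominant thermal response, each species gets broad secondary
    Gaussian responses to ``secondary_vars``, centred on the median ambient
    conditions inside its thermal range with breadth ``secondary_breadth_scale``
    times their spread — niches are genuinely multivariate (as the models
    downstream assume) while the secondary responses stay permissive enough
    not to distort the thermal overlap structure.

    Returns the pool and the realized intercept ``c`` of the OLS fit of
    ``ln S_true`` on ``1/kT`` over the grid's temperature span.
    """
    if activation_energy < 0:
        raise ValueError("activation_energy must be >= 0")
    Tvals = env["T"].values
    finite_T = np.isfinite(Tvals)
    t_lo = float(Tvals[finite_T].min())
    t_hi = float(Tvals[finite_T].max())
    w = range_width
    rng = np.random.default_rng(seed)

    # inverse-CDF sampling of midpoints with density ~ exp(-E/kT)
    m_lo, m_hi = t_lo - w / 2.0, t_hi + w / 2.0
    grid = np.linspace(m_lo, m_hi, 4001)
    dens = np.exp(-activation_energy / (K_BOLTZMANN_EV * (grid + CELSIUS_OFFSET)))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
    cdf /= cdf[-1]
    mids = np.interp(rng.random(n_species), cdf, grid)

    if n_species < 50:
        warnings.warn("few species: thermal gradient in overlap count is noisy")

    sec_fields = {
        v: env[v].values for v in secondary_vars if v in env.data_vars
    }
    pool = []
    for i, mid in enumerate(mids):
        niche = {"T": (float(mid), w / 4.0)}
        in_range = finite_T & (Tvals >= mid - w / 2.0) & (Tvals <= mid + w / 2.0)
        for var, vals in sec_fields.items():
            ambient = vals[in_range & np.isfinite(vals)]
            if ambient.size < 10:
                continue
            opt = float(np.median(ambient))
            breadth = float(
                max(secondary_breadth_scale * ambient.std(), 1e-3)
            )
            niche[var] = (opt, breadth)
        pool.append(
            SpeciesTruth(
                species_id=f"sp{i:04d}",
                taxon="virtual",
                niche=niche,
                p_max=p_max,
                thermal_range=(float(mid - w / 2.0), float(mid + w / 2.0)),
            )
        )

    tgrid = np.linspace(t_lo, t_hi, 200)
    counts = true_overlap_count(pool, tgrid)
    ok = counts > 0
    x = 1.0 / (K_BOLTZMANN_EV * (tgrid[ok] + CELSIUS_OFFSET))
    slope, intercept = np.polyfit(x, np.log(counts[ok]), 1)
    return pool, float(intercept)


def true_overlap_count(pool: Sequence[SpeciesTruth], temperatures) -> np.ndarray:
    """Number of species whose true thermal range covers each temperature."""
    temperatures = np.asarray(temperatures, dtype=float)
    lo = np.array([s.thermal_range[0] for s in pool if s.thermal_range])
    hi = np.array([s.thermal_range[1] for s in pool if s.thermal_range])
    return (
        (temperatures[:, None] >= lo[None, :])
        & (temperatures[:, None] <= hi[None, :])
    ).sum(axis=1)


# ---------------------------------------------------------------------------
# sampling effort and occurrence records
# ---------------------------------------------------------------------------


@dataclass
class EffortModel:
    """Relative sampling intensity per (month, lat, lon) cell."""

    intensity: np.ndarray  # shape (12, n_lat, n_lon), >= 0

    def __post_init__(self):
        if np.any(self.intensity < 0) or not np.any(self.intensity > 0):
            raise ValueError("effort must be >= 0 and not all zero")


def biased_effort(
    spec: GridSpec,
    env: xr.Dataset,
    hotspot_share: float = 0.49,
    seed: int = 0,
) -> EffortModel:
    """Effort field with one heavily sampled basin analogue.

    A northern-hemisphere longitude sector (~15% of ocean cells) receives
    ``hotspot_share`` of the total intensity, mirroring the North Atlantic's
    dominance in historical phytoplankton sampling; the remainder is spread
    smoothly elsewhere.  Land cells get zero effort.
    """
    rng = np.random.default_rng(seed)
    ocean = np.isfinite(env["T"].values)  # (12, nlat, nlon)
    base = 1.0 + 0.5 * np.abs(
        _smooth_noise(rng, (spec.n_lat, spec.n_lon), 2.0)
    )
    intensity = np.tile(base, (12, 1, 1))
    intensity[~ocean] = 0.0

    lat = spec.lat_centers
    lon = spec.lon_centers
    north = lat > (spec.lat_min + 0.55 * spec.n_lat)
    sector = (lon >= spec.lon_min) & (
        lon < spec.lon_min + 0.35 * spec.n_lon
    )
    hot = np.zeros((spec.n_lat, spec.n_lon), bool)
    hot[np.ix_(north, sector)] = True
    hot3 = np.tile(hot, (12, 1, 1)) & ocean

    tot = intensity.sum()
    hot_tot = intensity[hot3].sum()
    rest_tot = tot - hot_tot
    if hot_tot > 0 and rest_tot > 0 and 0 < hotspot_share < 1:
        intensity[hot3] *= (hotspot_share / (1 - hotspot_share)) * (
            rest_tot / hot_tot
        )
    return EffortModel(intensity=intensity)


def uniform_effort(spec: GridSpec, env: xr.Dataset) -> EffortModel:
    ocean = np.isfinite(env["T"].values).astype(float)
    return EffortModel(intensity=ocean)


@dataclass
class SamplingConfig:
    """Rates of the data-quality defects the cleaning stage must handle."""

    year_window: tuple = (1950, 2000)
    year_mean: float = 1984.0
    year_sd: float = 17.0
    depth_mean: float = 5.4
    depth_sd: float = 7.0
    missing_depth_rate: float = 0.15
    fossil_rate: float = 0.01
    preserved_rate: float = 0.01
    bad_year_rate: float = 0.005
    bad_coord_rate: float = 0.002


OCCURRENCE_COLUMNS = [
    "species_id",
    "lat",
    "lon",
    "depth",
    "year",
    "month",
    "day",
    "basis",
]

_DWC_MAP = {
    "species_id": "scientificName",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "depth": "depth",
    "year": "year",
    "month": "month",
    "day": "day",
    "basis": "basisOfRecord",
}


def sample_occurrences(
    pool: Sequence[SpeciesTruth],
    env: xr.Dataset,
    effort: EffortModel,
    n_samples: int,
    seed: int = 0,
    config: SamplingConfig | None = None,
) -> pd.DataFrame:
    """Draw presence-only records from ``n_samples`` effort-weighted visits.

    Each visit is a (month, cell) sampling event drawn proportionally to the
    effort intensity; every species in the pool is recorded at the visit with
    probability equal to its suitability there.  Records carry coordinates
    uniform within the cell, a sampling date, a depth (sometimes missing) and
    a basis-of-record flag, with configurable rates of the defects the
    cleaning rules target.
    """
    cfg = config or SamplingConfig()
    from .grid import grid_of

    spec = grid_of(env)
    rng = np.random.default_rng(seed)
    inten = effort.intensity.reshape(-1)
    if inten.sum() <= 0:
        raise ValueError("effort is all zero")
    p = inten / inten.sum()
    visits = rng.choice(inten.size, size=n_samples, p=p)
    vm, vi, vj = np.unravel_index(visits, effort.intensity.shape)
    vm = vm + 1  # month 1..12

    vlat = spec.lat_centers[vi] - 0.5 + rng.random(n_samples)
    vlon = spec.lon_centers[vj] - 0.5 + rng.random(n_samples)
    lo, hi = cfg.year_window
    vyear = np.clip(
        np.round(rng.normal(cfg.year_mean, cfg.year_sd, n_samples)), lo, hi
    ).astype(int)
    vday = rng.integers(1, 29, n_samples)
    vdepth = np.abs(rng.normal(cfg.depth_mean, cfg.depth_sd, n_samples))

    parts = []
    for sp in pool:
        suit = sp.suitability(env).values[vm - 1, vi, vj]
        suit = np.nan_to_num(suit, nan=0.0)
        hit = rng.random(n_samples) < suit
        if not hit.any():
            continue
        parts.append(
            pd.DataFrame(
                {
                    "species_id": sp.species_id,
                    "lat": vlat[hit],
                    "lon": vlon[hit],
                    "depth": vdepth[hit],
                    "year": vyear[hit],
                    "month": vm[hit],
                    "day": vday[hit],
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    rec = pd.concat(parts, ignore_index=True)
    n = len(rec)

    basis = np.full(n, "HumanObservation", dtype=object)
    u = rng.random(n)
    basis[u < cfg.fossil_rate] = "fossil specimen"
    basis[(u >= cfg.fossil_rate) & (u < cfg.fossil_rate + cfg.preserved_rate)] = (
        "preserved specimen"
    )
    rec["basis"] = basis
    miss = rng.random(n) < cfg.missing_depth_rate
    rec.loc[miss, "depth"] = np.nan
    bad_year = rng.random(n) < cfg.bad_year_rate
    rec.loc[bad_year, "year"] = rng.choice([1700, 2020], size=int(bad_year.sum()))
    bad_coord = rng.random(n) < cfg.bad_coord_rate
    rec.loc[bad_coord, "lat"] = rng.uniform(91.0, 120.0, int(bad_coord.sum()))
    return rec[OCCURRENCE_COLUMNS]


def write_occurrences(records: pd.DataFrame, path) -> None:
    """Write records as CSV with DarwinCore-style headers."""
    records.rename(columns=_DWC_MAP).to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    inv = {v: k for k, v in _DWC_MAP.items()}
    return df.rename(columns=inv)[OCCURRENCE_COLUMNS]
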