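"""Stacked richness, monthly species turnover, and Monte Carlo uncertainty.

Richness per monthly cell is the (optionally taxon-weighted) sum of the
species' ensemble values — the expected number of species present.  Turnover
between consecutive months uses the species-replacement component of Jaccard
dissimilarity on communities thresholded at ensemble value > 0.5, averaged
over the twelve month pairs (December-January wraps).  Predictor-set
uncertainty is quantified by re-stacking with one of each species' five
member predictor sets drawn at random per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .ensemble import EnsembleProjection


# ---------------------------------------------------------------------------
# taxon balancing
# ---------------------------------------------------------------------------


def taxon_weights(modeled: dict, known: dict, species_taxon: dict) -> dict:
    """Per-species weights balancing the taxonomic coverage of the stack.

    Species of taxon g get weight proportional to known_g / modeled_g (the
    inverse of the fraction of the taxon captured by the models), normalized
    so the weights of all modeled species sum to the modeled species count.
    Taxa with zero modeled species contribute nothing.
    """
    raw = {}
    for sp, tax in species_taxon.items():
        m = modeled.get(tax, 0)
        k = known.get(tax, 0)
        if m <= 0:
            continue
        if k < m:
            raise ValueError(f"taxon {tax}: known ({k}) < modeled ({m})")
        raw[sp] = k / m
    if not raw:
        return {}
    total = sum(raw.values())
    n = len(raw)
    return {sp: w * n / total for sp, w in raw.items()}


# ---------------------------------------------------------------------------
# richness stacking
# ---------------------------------------------------------------------------


@dataclass
class RichnessMap:
    monthly: xr.DataArray        # (month, lat, lon) expected richness
    annual_mean: xr.DataArray    # (lat, lon) mean over covered months
    months_covered: xr.DataArray  # (lat, lon) count of months with data

    @property
    def full_coverage(self) -> xr.DataArray:
        """True where all 12 months have data (partial-coverage caveat)."""
        return self.months_covered == 12


def stack_richness(
    ensembles: list[EnsembleProjection], weights: dict | None = None
) -> RichnessMap:
    """Sum per-species ensemble values into expected richness per cell.

    A species contributes its ensemble value (times its weight) to every
    monthly cell where its projection is defined; cells where no species has
    data in a month are NaN for that month, and the annual mean averages the
    covered months only.
    """
    if not ensembles:
        raise ValueError("no ensembles to stack")
    first = ensembles[0].data
    total = np.zeros(first.shape)
    covered = np.zeros(first.shape, dtype=bool)
    for ens in ensembles:
        w = 1.0 if weights is None else weights.get(ens.species_id, 0.0)
        vals = ens.data.values
        ok = np.isfinite(vals)
        total[ok] += w * vals[ok]
        covered |= ok
    total = np.where(covered, total, np.nan)
    monthly = xr.DataArray(
        total, coords=first.coords, dims=first.dims, name="richness"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        annual = monthly.mean(dim="month", skipna=True)
        months_covered = np.isfinite(monthly).sum(dim="month")
    return RichnessMap(monthly, annual, months_covered)


# ---------------------------------------------------------------------------
# turnover
# ---------------------------------------------------------------------------


def jaccard_turnover(a_set, b_set) -> float:
    """Species-replacement (turnover) component of Jaccard dissimilarity.

    With a shared species, b and c unique to either side:
    ``2 min(b, c) / (a + 2 min(b, c))``.  Pure nestedness gives 0; disjoint
    nonempty communities give 1.  Undefined (error) when both sides are
    empty.
    """
    A, B = set(a_set), set(b_set)
    if not A and not B:
        raise ValueError("turnover undefined for two empty communities")
    a = len(A & B)
    m = min(len(A - B), len(B - A))
    if a + m == 0:
        return 0.0
    return 2.0 * m / (a + 2.0 * m)


@dataclass
class TurnoverMap:
    mean: xr.DataArray       # (lat, lon) mean turnover over defined pairs
    per_pair: xr.DataArray   # (pair, lat, lon), pair p = months p+1 -> p+2


def turnover_map(
    ensembles: list[EnsembleProjection],
    presence_cut: float = 0.5,
    wrap: bool = True,
) -> TurnoverMap:
    """Mean month-to-month turnover per cell from thresholded communities.

    A species is present in a monthly cell when its ensemble value is
    strictly greater than ``presence_cut``.  Turnover is computed for every
    consecutive month pair (12 pairs including December-January when
    ``wrap``, else 11) and averaged per cell over the pairs where at least
    one side has a nonempty community and both months have data.
    """
    first = ensembles[0].data
    vals = np.stack([e.data.values for e in ensembles])  # (sp, 12, lat, lon)
    present = vals > presence_cut
    defined = np.isfinite(vals).all(axis=0)  # (12, lat, lon)

    pairs = [(m, (m + 1) % 12) for m in range(12 if wrap else 11)]
    out = np.full((len(pairs), *first.shape[1:]), np.nan)
    for k, (m1, m2) in enumerate(pairs):
        A = present[:, m1]
        B = present[:, m2]
        a = (A & B).sum(axis=0).astype(float)
        b = (A & ~B).sum(axis=0).astype(float)
        c = (~A & B).sum(axis=0).astype(float)
        m = np.minimum(b, c)
        denom = a + 2 * m
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, 2 * m / denom, 0.0)
        empty_both = (a + b + c) == 0
        t = np.where(empty_both, np.nan, t)
        t = np.where(defined[m1] & defined[m2], t, np.nan)
        out[k] = t

    per_pair = xr.DataArray(
        out,
        coords={
            "pair": np.arange(1, len(pairs) + 1),
            "lat": first["lat"],
            "lon": first["lon"],
        },
        dims=("pair", "lat", "lon"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = per_pair.mean(dim="pair", skipna=True)
    return TurnoverMap(mean, per_pair)


# ---------------------------------------------------------------------------
# Monte Carlo over predictor sets
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloSummary:
    richness_mean: xr.DataArray
    richness_sd: xr.DataArray
    turnover_mean: xr.DataArray
    turnover_sd: xr.DataArray
    n_runs: int
    seed: int
    n_failed: int = 0


def monte_carlo_diversity(
    member_projections: dict,
    n_runs: int = 1000,
    seed: int = 0,
    weights: dict | None = None,
    presence_cut: float = 0.5,
) -> MonteCarloSummary:
    """Per-cell spread of richness and turnover over random predictor sets.

    ``member_projections`` maps species_id -> list of
    :class:`EnsembleProjection`-like single-set projections (one per
    retained predictor set of that species; member fits are deterministic
    given their set, so they are fitted once and reused across runs).  Each
    run draws one projection per species uniformly at random, stacks
    richness and turnover, and the summary reports the per-cell mean and SD
    across runs.
    """
    rng = np.random.default_rng(seed)
    species = sorted(member_projections)
    r_acc, r2_acc, t_acc, t2_acc = None, None, None, None
    n_failed = 0
    for _run in range(n_runs):
        picks = []
        for sp in species:
            opts = member_projections[sp]
            picks.append(opts[rng.integers(len(opts))])
        try:
            rich = stack_richness(picks, weights).monthly.values
            turn = turnover_map(picks, presence_cut).mean.values
        except Exception:
            n_failed += 1
            continue
        rich = np.nan_to_num(rich, nan=np.nan)
        if r_acc is None:
            r_acc = np.zeros_like(rich)
            r2_acc = np.zeros_like(rich)
            t_acc = np.zeros_like(turn)
            t2_acc = np.zeros_like(turn)
        r_acc += rich
        r2_acc += rich ** 2
        t_acc += turn
        t2_acc += turn ** 2
    n_ok = n_runs - n_failed
    if n_ok == 0:
        raise RuntimeError("all Monte Carlo runs failed")
    template = member_projections[species[0]][0].data
    mcoords = {"month": template["month"], "lat": template["lat"], "lon": template["lon"]}
    ccoords = {"lat": template["lat"], "lon": template["lon"]}

    def _da(arr, coords, dims):
        return xr.DataArray(arr, coords=coords, dims=dims)

    r_mean = r_acc / n_ok
    r_sd = np.sqrt(np.maximum(r2_acc / n_ok - r_mean ** 2, 0.0))
    t_mean = t_acc / n_ok
    t_sd = np.sqrt(np.maximum(t2_acc / n_ok - t_mean ** 2, 0.0))
    return MonteCarloSummary(
        richness_mean=_da(r_mean, mcoords, ("month", "lat", "lon")),
        richness_sd=_da(r_sd, mcoords, ("month", "lat", "lon")),
        turnover_mean=_da(t_mean, ccoords, ("lat", "lon")),
        turnover_sd=_da(t_sd, ccoords, ("lat", "lon")),
        n_runs=n_runs,
        seed=seed,
        n_failed=n_failed,
    )
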