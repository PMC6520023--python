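"""Macroecological analyses downstream of the richness and turnover maps.

Covers the Boltzmann-axis regressions of log richness on inverse thermal
energy (with the three thermal regimes split at 11 and 19 deg C), the
single-variable explanatory power of environmental fields for richness,
rarefied richness in the raw observations, and the species-range overlap
analysis with its label-randomization null model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import CELSIUS_OFFSET, K_BOLTZMANN_EV

#: Default regime breakpoints (deg C) on the annual-mean temperature axis.
DEFAULT_BREAKPOINTS = (11.0, 19.0)


def inverse_thermal_energy(t_celsius) -> np.ndarray:
    """x = 1 / (k T) with T in kelvin and k in eV/K; units 1/eV."""
    return 1.0 / (K_BOLTZMANN_EV * (np.asarray(t_celsius, float) + CELSIUS_OFFSET))


@dataclass
class RegimeFit:
    """Piecewise OLS of ln(richness) on 1/kT, per thermal regime and global."""

    breakpoints: tuple
    fits: dict = field(default_factory=dict)  # name -> dict(slope, intercept, r2, n)

    def slope(self, name: str) -> float:
        return self.fits[name]["slope"]


def _ols(x, y):
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r2": float(res.rsquared),
        "n": int(res.nobs),
    }


def fit_thermal_regimes(
    richness,
    temperature,
    breakpoints=DEFAULT_BREAKPOINTS,
) -> RegimeFit:
    """Regress ln(richness) on inverse thermal energy within thermal regimes.

    ``richness`` and ``temperature`` are paired per-cell annual means
    (arrays of any shape).  Cells with missing or non-positive richness are
    dropped.  Regimes are ``warm`` (T > upper breakpoint), ``mid`` (between
    the breakpoints), ``cold`` (T < lower breakpoint) and ``global`` (all
    cells); regimes with fewer than 3 cells are skipped and reported with
    n only.
    """
    r = np.asarray(richness, float).reshape(-1)
    t = np.asarray(temperature, float).reshape(-1)
    ok = np.isfinite(r) & np.isfinite(t) & (r > 0)
    r, t = r[ok], t[ok]
    x = inverse_thermal_energy(t)
    y = np.log(r)
    lo, hi = sorted(breakpoints)
    masks = {
        "warm": t > hi,
        "mid": (t >= lo) & (t <= hi),
        "cold": t < lo,
        "global": np.ones(t.size, dtype=bool),
    }
    out = RegimeFit(breakpoints=tuple(sorted(breakpoints)))
    for name, m in masks.items():
        if m.sum() < 3:
            out.fits[name] = {"slope": np.nan, "intercept": np.nan,
                              "r2": np.nan, "n": int(m.sum())}
            continue
        out.fits[name] = _ols(x[m], y[m])
    return out


def search_breakpoints(
    richness, temperature, grid_step: float = 1.0, min_gap: float = 3.0
) -> tuple:
    """Two-breakpoint grid search minimizing the pooled three-regime SSE."""
    r = np.asarray(richness, float).reshape(-1)
    t = np.asarray(temperature, float).reshape(-1)
    ok = np.isfinite(r) & np.isfinite(t) & (r > 0)
    r, t = r[ok], t[ok]
    x = inverse_thermal_energy(t)
    y = np.log(r)
    cands = np.arange(np.floor(t.min()) + 2, np.ceil(t.max()) - 2, grid_step)
    best, best_sse = None, np.inf
    for lo in cands:
        for hi in cands[cands >= lo + min_gap]:
            sse = 0.0
            for m in (t < lo, (t >= lo) & (t <= hi), t > hi):
                if m.sum() < 3:
                    sse = np.inf
                    break
                p = np.polyfit(x[m], y[m], 1)
                sse += float(np.sum((y[m] - np.polyval(p, x[m])) ** 2))
            if sse < best_sse:
                best_sse = sse
                best = (float(lo), float(hi))
    return best


def single_variable_power(response, predictor) -> float:
    """R-squared of a single-predictor (linear + quadratic) model of richness.

    Gaussian family on the untransformed response, so scores are comparable
    across predictors.  Constant predictors score 0.
    """
    y = np.asarray(response, float).reshape(-1)
    x = np.asarray(predictor, float).reshape(-1)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 10:
        raise ValueError("need at least 10 paired values")
    if np.std(x) == 0:
        return 0.0
    X = sm.add_constant(np.column_stack([x, x ** 2]))
    res = sm.OLS(y, X).fit()
    return float(res.rsquared)


def power_table(response, predictors: dict) -> pd.DataFrame:
    """Single-variable explanatory power for each predictor, sorted."""
    rows = [
        {"predictor": name, "r2": single_variable_power(response, vals)}
        for name, vals in predictors.items()
    ]
    return (
        pd.DataFrame(rows).sort_values("r2", ascending=False, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# rarefied raw-data richness
# ---------------------------------------------------------------------------

SAMPLE_KEY = ["lat", "lon", "depth", "year", "month", "day"]


def rarefied_raw_richness(
    records: pd.DataFrame,
    strata: pd.Series | np.ndarray,
    n_per_stratum: int,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefied species richness per stratum of the raw observations.

    A "sample" is a unique (lat, lon, depth, year, month, day) collection
    event.  Per repetition, ``n_per_stratum`` samples are drawn without
    replacement from each stratum, their records pooled, and distinct
    species counted.  Strata with fewer samples than requested are excluded
    and reported with NaN.  Returns per-stratum mean and SD over reps plus
    the available sample count.
    """
    rng = np.random.default_rng(seed)
    rec = records.copy()
    rec["_stratum"] = np.asarray(strata)
    key = rec[SAMPLE_KEY].astype(str).agg("|".join, axis=1)
    rec["_sample"] = key
    rows = []
    for stratum, sub in rec.groupby("_stratum"):
        samples = sub["_sample"].unique()
        if samples.size < n_per_stratum:
            rows.append(
                {"stratum": stratum, "mean_richness": np.nan,
                 "sd_richness": np.nan, "n_samples": samples.size}
            )
            continue
        by_sample = sub.groupby("_sample")["species_id"].agg(set)
        vals = []
        for _ in range(n_reps):
            take = rng.choice(samples, size=n_per_stratum, replace=False)
            pooled = set().union(*by_sample.loc[take])
            vals.append(len(pooled))
        rows.append(
            {"stratum": stratum, "mean_richness": float(np.mean(vals)),
             "sd_richness": float(np.std(vals)), "n_samples": samples.size}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species ranges and the overlap null model
# ---------------------------------------------------------------------------


def observed_range(values) -> dict:
    """Min, max and median of a species' matched environmental values."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no matchable records")
    return {"min": float(v.min()), "max": float(v.max()),
            "median": float(np.median(v))}


def species_ranges(records: pd.DataFrame, values: np.ndarray) -> pd.DataFrame:
    """Observed (min, max, median) per species of matched values."""
    df = pd.DataFrame(
        {"species_id": records["species_id"].values, "value": np.asarray(values)}
    ).dropna()
    g = df.groupby("species_id")["value"]
    out = g.agg(["min", "max", "median"]).reset_index()
    return out


def range_overlap_curves(ranges: pd.DataFrame, value_grid) -> pd.DataFrame:
    """Expected maximum richness and mean range size along a gradient.

    At each grid value v: richness = number of species whose [min, max]
    range covers v; range size = mean (and SD) of (max - min) over those
    species.  Grid values covered by no species get NaN curves.
    """
    if ranges.empty:
        raise ValueError("no species ranges")
    v = np.asarray(value_grid, float)
    lo = ranges["min"].to_numpy(float)
    hi = ranges["max"].to_numpy(float)
    size = hi - lo
    cover = (v[:, None] >= lo[None, :]) & (v[:, None] <= hi[None, :])
    count = cover.sum(axis=1)
    mean_size = np.full(v.size, np.nan)
    sd_size = np.full(v.size, np.nan)
    nz = count > 0
    for i in np.where(nz)[0]:
        s = size[cover[i]]
        mean_size[i] = s.mean()
        sd_size[i] = s.std()
    return pd.DataFrame(
        {"value": v, "overlap_richness": count,
         "mean_range_size": mean_size, "sd_range_size": sd_size}
    )


def range_null_model(
    records: pd.DataFrame,
    values: np.ndarray,
    value_grid,
    n_runs: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    center_fraction: float = 0.5,
) -> pd.DataFrame:
    """Randomization null envelope for the range-overlap curves.

    Each run shuffles species labels across the occurrence records (keeping
    every species' record count and the pooled environmental distribution
    fixed), recomputes the overlap and range-size curves, and the envelope is
    the per-value mean and central ``1 - alpha`` interval across runs.  Grid
    values where the richness envelope departs from the envelope's central
    level — the null curve's mean over the middle ``center_fraction`` of the
    observed gradient span, judged against the interval — are flagged as
    edge-affected.
    """
    if n_runs < 20:
        warnings.warn("n_runs < 20 gives an unstable null envelope")
    rng = np.random.default_rng(seed)
    v = np.asarray(value_grid, float)
    vals = np.asarray(values, float)
    labels = records["species_id"].to_numpy()
    rich = np.empty((n_runs, v.size))
    rsize = np.empty((n_runs, v.size))
    for run in range(n_runs):
        shuffled = labels[rng.permutation(labels.size)]
        rec = pd.DataFrame({"species_id": shuffled})
        rr = species_ranges(rec, vals)
        curves = range_overlap_curves(rr, v)
        rich[run] = curves["overlap_richness"].to_numpy(float)
        rsize[run] = curves["mean_range_size"].to_numpy(float)

    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = pd.DataFrame({"value": v})
    out["null_richness_mean"] = rich.mean(axis=0)
    out["null_richness_lo"] = np.percentile(rich, qlo, axis=0)
    out["null_richness_hi"] = np.percentile(rich, qhi, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["null_range_size_mean"] = np.nanmean(rsize, axis=0)
        out["null_range_size_lo"] = np.nanpercentile(rsize, qlo, axis=0)
        out["null_range_size_hi"] = np.nanpercentile(rsize, qhi, axis=0)

    finite = vals[np.isfinite(vals)]
    span = finite.max() - finite.min()
    pad = (1 - center_fraction) / 2 * span
    center = (v >= finite.min() + pad) & (v <= finite.max() - pad)
    center_level = float(out.loc[center, "null_richness_mean"].mean())
    out["edge_affected"] = (out["null_richness_lo"] > center_level) | (
        out["null_richness_hi"] < center_level
    )
    return out
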