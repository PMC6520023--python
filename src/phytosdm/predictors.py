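"""Derived environmental predictors and single-predictor skill ranking.

Secondary predictors capture nutrient stoichiometry (N-star, Si-star), light
integrated over the mixing depth (MLPAR), month-to-month tendencies of the
seasonal fields, and log transforms of the skewed ones.  Candidate predictors
are then ranked per species by the skill of single-predictor presence-vs-
background models: adjusted D-squared for GLM and GAM, out-of-bag skill for
random forest, averaged into a mean rank.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import rankdata

from .glm import fit_logistic
from .grid import field_at

#: Redfield N:P ratio used for the nitrate-excess predictor.
REDFIELD_N_TO_P = 16.0

TREND_SOURCES = ("T", "NO3", "PO4", "SiOH4", "MLD")
LOG_SOURCES = ("MLD", "Chl", "NO3", "PO4", "SiOH4")

#: Default candidate list for the single-predictor skill test: the ten raw
#: fields plus the derived and log-transformed ones (~25 candidates).
DEFAULT_CANDIDATES = (
    "T", "S", "NO3", "PO4", "SiOH4", "MLD", "PAR", "Chl", "wind", "pCO2",
    "N_star", "Si_star", "MLPAR",
    "dT_dt", "dNO3_dt", "dPO4_dt", "dSiOH4_dt", "dMLD_dt",
    "logMLD", "logChl", "logNO3", "logPO4", "logSiOH4",
)


def attenuation_coefficient(chl: xr.DataArray) -> xr.DataArray:
    """Diffuse light attenuation kd (1/m) from chlorophyll (ug/L)."""
    return 0.04 + 0.0088 * chl + 0.054 * chl ** (2.0 / 3.0)


def derive_predictors(env: xr.Dataset) -> xr.Dataset:
    """Return ``env`` augmented with the derived predictor fields.

    * ``N_star`` = NO3 - 16 PO4 (nitrate excess over Redfield, uM)
    * ``Si_star`` = SiOH4 / NO3 (missing where NO3 == 0)
    * ``MLPAR`` = PAR averaged over the mixed layer assuming exponential
      attenuation: PAR * (1 - exp(-kd MLD)) / (kd MLD)
    * ``dX_dt`` = centred difference (X[m+1] - X[m-1]) / 2 with December and
      January wrapping around
    * ``logX`` = log10 of X (missing where X <= 0)

    Derived fields whose sources are absent are omitted with a warning.
    """
    out = env.copy()
    have = set(env.data_vars)

    if {"NO3", "PO4"} <= have:
        out["N_star"] = env["NO3"] - REDFIELD_N_TO_P * env["PO4"]
    else:
        warnings.warn("NO3/PO4 missing; N_star omitted")
    if {"SiOH4", "NO3"} <= have:
        out["Si_star"] = env["SiOH4"] / env["NO3"].where(env["NO3"] > 0)
    else:
        warnings.warn("SiOH4/NO3 missing; Si_star omitted")
    if {"PAR", "MLD", "Chl"} <= have:
        kd = attenuation_coefficient(env["Chl"])
        tau = kd * env["MLD"]
        out["MLPAR"] = env["PAR"] * (1.0 - np.exp(-tau)) / tau
    else:
        warnings.warn("PAR/MLD/Chl missing; MLPAR omitted")

    for var in TREND_SOURCES:
        if var not in have:
            continue
        x = env[var]
        out[f"d{var}_dt"] = (x.roll(month=-1) - x.roll(month=1)) / 2.0
    for var in LOG_SOURCES:
        if var not in have:
            continue
        out[f"log{var}"] = np.log10(env[var].where(env[var] > 0))
    return out


def adjusted_d2(
    null_deviance: float, residual_deviance: float, n: int, p: int
) -> float:
    """Deviance-based explained variation, penalized for parameter count.

    D2 = (null - residual) / null; adjusted D2 = 1 - ((n-1)/(n-p)) (1 - D2).
    """
    if null_deviance <= 0:
        raise ValueError("null_deviance must be > 0")
    if n <= p:
        raise ValueError("adjusted D2 undefined for n <= p")
    d2 = (null_deviance - residual_deviance) / null_deviance
    return 1.0 - ((n - 1) / (n - p)) * (1.0 - d2)


def matchup(
    presence_cells: pd.DataFrame,
    background_cells: pd.DataFrame,
    env: xr.Dataset,
    variables,
) -> pd.DataFrame:
    """Monthly environmental matchup of presence (1) and background (0) cells.

    Returns a frame with a ``label`` column and one column per variable;
    rows where every requested variable is missing are dropped.
    """
    frames = []
    for cells, label in ((presence_cells, 1), (background_cells, 0)):
        if cells.empty:
            continue
        d = {"label": np.full(len(cells), label, dtype=int)}
        for var in variables:
            d[var] = field_at(
                env,
                var,
                cells["month"].values,
                cells["lat_idx"].values,
                cells["lon_idx"].values,
            )
        f = pd.DataFrame(d)
        f["month"] = cells["month"].values
        f["lat_idx"] = cells["lat_idx"].values
        f["lon_idx"] = cells["lon_idx"].values
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    all_missing = out[list(variables)].isna().all(axis=1)
    return out.loc[~all_missing].reset_index(drop=True)


def presence_background_weights(labels: np.ndarray) -> np.ndarray:
    """Case weights equalizing total presence and background weight."""
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    w = np.ones(labels.size)
    if n0 > 0 and n1 > 0:
        w[labels == 0] = n1 / n0
    return w


def _quadratic_design(x: np.ndarray) -> np.ndarray:
    # standardized to keep IRLS well conditioned; invariant for D2/ranks
    mu, sd = np.nanmean(x), np.nanstd(x)
    sd = sd if sd > 0 else 1.0
    z = (x - mu) / sd
    return np.column_stack([np.ones(x.size), z, z ** 2])


def _glm_d2(x, y, w):
    X = _quadratic_design(x)
    fit = fit_logistic(X, y, w)
    return adjusted_d2(fit.null_deviance, fit.deviance, fit.n, 3)


def _gam_d2(x, y, w, df=5):
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    bs = BSplines(x[:, None], df=[df], degree=[3])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(
            y,
            np.ones((y.size, 1)),
            smoother=bs,
            family=sm.families.Binomial(),
            freq_weights=w,
        )
        res = model.fit()
    return adjusted_d2(res.null_deviance, res.deviance, y.size, df + 1)


def _rf_oob_skill(x, y, seed, n_trees):
    from sklearn.ensemble import RandomForestClassifier

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=1,
        oob_score=True,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(x[:, None], y)
    return rf.oob_score_  # 1 - OOB error


def rank_predictors(
    data: pd.DataFrame,
    candidates=DEFAULT_CANDIDATES,
    seed: int = 0,
    algorithms=("glm", "gam", "rf"),
    min_presences: int = 24,
    rf_trees: int = 200,
) -> pd.DataFrame:
    """Rank candidate predictors by single-predictor model skill.

    ``data`` is a labeled matchup frame (see :func:`matchup`).  For each
    candidate, single-predictor GLM (linear + quadratic) and GAM (smooth,
    five basis dimensions) are scored by adjusted D-squared and a random
    forest by out-of-bag skill (1 - OOB error); per-algorithm ranks (ties
    averaged) are combined into an ascending mean rank.  Non-converging or
    degenerate fits are assigned the worst score for that algorithm.

    Returns a frame indexed by candidate with score, rank and ``mean_rank``
    columns, sorted by mean rank.
    """
    n_pres = int((data["label"] == 1).sum())
    if n_pres < min_presences:
        raise ValueError(
            f"species has {n_pres} presences; minimum is {min_presences}"
        )
    y_all = data["label"].to_numpy(float)
    scores = {alg: [] for alg in algorithms}
    for cand in candidates:
        x = data[cand].to_numpy(float)
        ok = np.isfinite(x)
        x_, y_ = x[ok], y_all[ok]
        w_ = presence_background_weights(y_)
        degenerate = (
            y_.size < 10
            or np.unique(y_).size < 2
            or np.nanstd(x_) == 0
        )
        for alg in algorithms:
            if degenerate:
                scores[alg].append(-np.inf)
                continue
            try:
                if alg == "glm":
                    s = _glm_d2(x_, y_, w_)
                elif alg == "gam":
                    s = _gam_d2(x_, y_, w_)
                elif alg == "rf":
                    s = _rf_oob_skill(x_, y_.astype(int), seed, rf_trees)
                else:
                    raise ValueError(f"unknown algorithm {alg}")
                scores[alg].append(s if np.isfinite(s) else -np.inf)
            except Exception:
                warnings.warn(f"{alg} fit failed for {cand}; worst rank assigned")
                scores[alg].append(-np.inf)

    out = pd.DataFrame(index=list(candidates))
    rank_cols = []
    for alg in algorithms:
        s = np.array(scores[alg])
        out[f"score_{alg}"] = s
        ranks = rankdata(-s, method="average")
        out[f"rank_{alg}"] = ranks
        rank_cols.append(f"rank_{alg}")
    out["mean_rank"] = out[rank_cols].mean(axis=1)
    out.index.name = "predictor"
    return out.sort_values("mean_rank", kind="stable")
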