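"""Per-species SDM members (GLM / GAM / RF), evaluation, and ensembles.

Five member models per species, each on a different four-predictor set drawn
from the species' skill ranking under correlation (|Spearman rho| <= 0.7) and
reuse (each predictor in at most two sets) constraints.  Members are scored
by repeated (4x) split-sample cross-validated TSS, retained at TSS >= 0.35,
binarized at their max-TSS threshold and averaged into an ensemble map whose
cell values are the fraction of retained members projecting presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .glm import fit_logistic, predict_logistic, stepwise_logistic
from .predictors import presence_background_weights

TSS_MIN = 0.35


# ---------------------------------------------------------------------------
# predictor-set planning
# ---------------------------------------------------------------------------


def predictor_correlations(env: xr.Dataset, candidates) -> pd.DataFrame:
    """Pairwise Spearman correlations on global monthly gridded values."""
    cols = {}
    for var in candidates:
        cols[var] = env[var].values.reshape(-1)
    df = pd.DataFrame(cols)
    return df.corr(method="spearman")


def select_predictor_sets(
    ranking,
    correlations: pd.DataFrame,
    n_sets: int = 5,
    set_size: int = 4,
    corr_max: float = 0.7,
    reuse_max: int = 2,
    top_n: int = 10,
    seed: int = 0,
    max_retries: int = 200,
) -> list[tuple]:
    """Draw ``n_sets`` predictor sets of ``set_size`` from a skill ranking.

    ``ranking`` is the species' predictors ordered best first (a list or the
    index of :func:`phytosdm.predictors.rank_predictors` output).  Predictors
    are drawn at random without replacement from the species' ``top_n``,
    never pairing two with |Spearman rho| > ``corr_max`` and never using one
    in more than ``reuse_max`` sets; when those constraints exhaust the top
    ranks, lower-ranked candidates are admitted.  Raises ``ValueError`` when
    no valid plan exists even with the fallback.
    """
    order = list(ranking)
    rng = np.random.default_rng(seed)

    def compatible(p, chosen):
        return all(
            abs(correlations.loc[p, q]) <= corr_max for q in chosen
        )

    # a greedy pass can dead-end globally (early sets exhausting the scarce
    # weakly-correlated predictors), so whole plans are retried as well
    last_incomplete = 0
    for _plan_try in range(max_retries):
        usage = {p: 0 for p in order}
        sets = []
        for _si in range(n_sets):
            chosen = None
            for _try in range(10):
                top = [p for p in order[:top_n] if usage[p] < reuse_max]
                rest = [p for p in order[top_n:] if usage[p] < reuse_max]
                trial = []
                for pool in (rng.permutation(top), rng.permutation(rest)):
                    for p in pool:
                        if len(trial) == set_size:
                            break
                        if compatible(p, trial):
                            trial.append(p)
                if len(trial) == set_size:
                    chosen = trial
                    break
            if chosen is None:
                break
            for p in chosen:
                usage[p] += 1
            sets.append(tuple(chosen))
        if len(sets) == n_sets:
            return sets
        last_incomplete = len(sets)
    raise ValueError(
        f"cannot build {n_sets} predictor sets under the correlation/reuse "
        f"constraints (best attempt reached {last_incomplete})"
    )


# ---------------------------------------------------------------------------
# members
# ---------------------------------------------------------------------------


@dataclass
class MemberModel:
    """One fitted member of a species' SDM ensemble."""

    species_id: str
    algorithm: str           # "glm" | "gam" | "rf"
    predictors: tuple
    model: object = None     # algorithm-specific fitted state
    tss: float | None = None
    threshold: float | None = None

    @property
    def retained(self) -> bool:
        return self.tss is not None and self.tss >= TSS_MIN

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[list(self.predictors)].to_numpy(float)
        return _predict(self, X)


@dataclass
class _GlmState:
    mean: np.ndarray
    sd: np.ndarray
    selected: list        # indices into the full quadratic design
    coef: np.ndarray


def _glm_design(X, mean, sd):
    Z = (X - mean) / sd
    cols = [np.ones(len(X))]
    for j in range(Z.shape[1]):
        cols.append(Z[:, j])
        cols.append(Z[:, j] ** 2)
    return np.column_stack(cols)


def fit_member(
    train: pd.DataFrame,
    algorithm: str,
    predictors,
    seed: int = 0,
    species_id: str = "",
    rf_trees: int = 4000,
    stepwise: bool = True,
    gam_df: int = 5,
    gam_alpha: float = 1.0,
) -> MemberModel:
    """Fit one member model on a labeled presence/background matchup frame.

    GLM: linear + quadratic terms with bidirectional AIC stepwise selection;
    GAM: penalized regression splines with five basis dimensions and no
    shrinkage to zero; RF: 4000 trees, terminal node size 1, per-tree
    balanced subsampling of the background.  GLM and GAM weight background
    rows by n_presences / n_background so both classes carry equal total
    weight.  Rows with a missing predictor value are dropped.
    """
    predictors = tuple(predictors)
    cols = list(predictors)
    sub = train.dropna(subset=cols)
    y = sub["label"].to_numpy(float)
    X = sub[cols].to_numpy(float)
    w = presence_background_weights(y)
    member = MemberModel(species_id, algorithm, predictors)

    if algorithm == "glm":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        D = _glm_design(X, mean, sd)
        if stepwise:
            selected, fit = stepwise_logistic(D, y, w)
        else:
            selected = list(range(D.shape[1]))
            fit = fit_logistic(D, y, w)
        member.model = _GlmState(mean, sd, selected, fit.coef)
    elif algorithm == "gam":
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        bs = BSplines(X, df=[gam_df] * len(cols), degree=[3] * len(cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # mild fixed smoothing penalty: penalized regression splines that
            # never shrink a term to zero; escalate the penalty if the fit
            # runs into complete separation
            res = None
            alpha = gam_alpha
            for _attempt in range(4):
                try:
                    res = GLMGam(
                        y,
                        np.ones((y.size, 1)),
                        smoother=bs,
                        alpha=[alpha] * len(cols),
                        family=sm.families.Binomial(),
                        freq_weights=w,
                    ).fit()
                    break
                except Exception:
                    alpha *= 100.0
            if res is None:
                raise RuntimeError("GAM member failed to converge")
        member.model = {
            "result": res,
            "smoother": bs,
            "lo": X.min(axis=0),
            "hi": X.max(axis=0),
        }
    elif algorithm == "rf":
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(
            n_estimators=rf_trees,
            min_samples_leaf=1,
            class_weight="balanced_subsample",
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(X, y.astype(int))
        member.model = rf
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return member


def _predict(member: MemberModel, X: np.ndarray) -> np.ndarray:
    ok = np.all(np.isfinite(X), axis=1)
    out = np.full(len(X), np.nan)
    if not ok.any():
        return out
    Xo = X[ok]
    if member.algorithm == "glm":
        st: _GlmState = member.model
        D = _glm_design(Xo, st.mean, st.sd)[:, st.selected]
        out[ok] = predict_logistic(st.coef, D)
    elif member.algorithm == "gam":
        st = member.model
        # clamp to the training range: B-spline bases are undefined beyond it
        Xc = np.clip(Xo, st["lo"], st["hi"])
        basis = st["smoother"].transform(Xc)
        exog = np.column_stack([np.ones(len(Xc)), basis])
        res = st["result"]
        out[ok] = res.model.family.link.inverse(exog @ res.params)
    elif member.algorithm == "rf":
        out[ok] = member.model.predict_proba(Xo)[:, 1]
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def tss(tp: int, fp: int, fn: int, tn: int) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined with an empty class")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def max_tss_threshold(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold (on 'predict presence when prob >= t') maximizing TSS.

    Candidates are the unique predicted values; ties resolve to the lowest
    threshold.  Returns ``(threshold, tss_at_threshold)``.  With constant
    predictions the constant is returned with TSS 0 and a warning.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    ok = np.isfinite(probs)
    probs, labels = probs[ok], labels[ok]
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    uniq = np.unique(probs)
    if uniq.size == 1:
        warnings.warn("constant predictions; TSS is 0")
        return float(uniq[0]), 0.0
    # tp(t) = #presences with prob >= t ; fp(t) = #background with prob >= t
    order = np.argsort(probs, kind="stable")
    sp = probs[order]
    sl = labels[order]
    pos_below = np.searchsorted(sp, uniq, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(sl == 1)])
    cum_neg = np.concatenate([[0], np.cumsum(sl == 0)])
    tp = n1 - cum_pos[pos_below]
    fp = n0 - cum_neg[pos_below]
    # integer score n0*tp + n1*tn is an exact monotone image of the TSS,
    # so ties resolve exactly (lowest threshold wins)
    iscore = n0 * tp + n1 * (n0 - fp)
    k = int(np.argmax(iscore == iscore.max()))
    best = tp[k] / n1 + (n0 - fp[k]) / n0 - 1.0
    return float(uniq[k]), float(best)


def cross_validate(
    train: pd.DataFrame,
    algorithm: str,
    predictors,
    folds: int = 4,
    seed: int = 0,
    max_resplits: int = 5,
    **fit_kwargs,
) -> float:
    """Repeated split-sample cross-validated TSS of a member specification.

    The labeled data are split at random into ``folds`` parts; the member is
    refit (including any stepwise selection) on the other parts and predicts
    the held-out quarter.  The fold's threshold is the max-TSS threshold of
    the training predictions, and the fold TSS is evaluated on the held-out
    part at that threshold.  Returns the mean fold TSS.  Splits producing a
    single-class part are redrawn with a fresh sub-seed.
    """
    sub = train.dropna(subset=list(predictors)).reset_index(drop=True)
    y = sub["label"].to_numpy(int)
    n = len(sub)
    rng = np.random.default_rng(seed)
    for attempt in range(max_resplits):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        ok = all(
            np.unique(y[fold_of == f]).size == 2 for f in range(folds)
        )
        if ok:
            break
    else:
        raise ValueError("could not split data into folds with both classes")

    glm_fast = algorithm == "glm" and fit_kwargs.get("stepwise", True)
    if glm_fast:
        X = sub[list(predictors)].to_numpy(float)

    scores = []
    for f in range(folds):
        tr_mask = fold_of != f
        if glm_fast:
            # numpy fast path: same model contract, no per-fold frame rebuild
            Xtr, ytr = X[tr_mask], y[tr_mask].astype(float)
            w = presence_background_weights(ytr)
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            D = _glm_design(X, mean, sd)
            selected, fit = stepwise_logistic(D[tr_mask], ytr, w)
            p_tr = predict_logistic(fit.coef, D[tr_mask][:, selected])
            p = predict_logistic(fit.coef, D[~tr_mask][:, selected])
        else:
            tr = sub.loc[tr_mask]
            m = fit_member(
                tr, algorithm, predictors, seed=seed + 101 * f, **fit_kwargs
            )
            p_tr = m.predict(tr)
            p = m.predict(sub.loc[~tr_mask])
        thr, _ = max_tss_threshold(p_tr, y[tr_mask])
        yy = y[~tr_mask]
        pred = p >= thr
        tp = int(np.sum(pred & (yy == 1)))
        fp = int(np.sum(pred & (yy == 0)))
        fn = int(np.sum(~pred & (yy == 1)))
        tn = int(np.sum(~pred & (yy == 0)))
        scores.append(tss(tp, fp, fn, tn))
    return float(np.mean(scores))


def build_member(
    train: pd.DataFrame,
    algorithm: str,
    predictors,
    seed: int = 0,
    species_id: str = "",
    folds: int = 4,
    **fit_kwargs,
) -> MemberModel:
    """Fit, cross-validate and threshold one member model.

    The deployed binarization threshold is refit on the full calibration
    predictions; the stored TSS is the cross-validated mean.
    """
    member = fit_member(
        train, algorithm, predictors, seed=seed, species_id=species_id,
        **fit_kwargs,
    )
    member.tss = cross_validate(
        train, algorithm, predictors, folds=folds, seed=seed, **fit_kwargs
    )
    sub = train.dropna(subset=list(predictors))
    thr, _ = max_tss_threshold(
        member.predict(sub), sub["label"].to_numpy(int)
    )
    member.threshold = thr
    return member


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _env_frame(env: xr.Dataset, predictors) -> tuple[pd.DataFrame, tuple]:
    shape = (env.sizes["month"], env.sizes["lat"], env.sizes["lon"])
    cols = {v: env[v].values.reshape(-1) for v in predictors}
    return pd.DataFrame(cols), shape


def project_member(member: MemberModel, env: xr.Dataset) -> xr.DataArray:
    """Binary monthly presence map: probability >= threshold.

    Cells where any predictor of the member's set is missing are NaN, not
    absence.
    """
    if member.threshold is None:
        raise ValueError("member has no threshold; run build_member first")
    frame, shape = _env_frame(env, member.predictors)
    probs = member.predict(frame)
    binary = np.where(np.isfinite(probs), (probs >= member.threshold) * 1.0, np.nan)
    return xr.DataArray(
        binary.reshape(shape),
        coords={"month": env["month"], "lat": env["lat"], "lon": env["lon"]},
        dims=("month", "lat", "lon"),
        name=f"{member.species_id}_{member.algorithm}",
    )


@dataclass
class EnsembleProjection:
    """Fraction of retained members projecting presence, per monthly cell."""

    species_id: str
    data: xr.DataArray        # (month, lat, lon) in [0, 1]
    n_members: int
    member_tss: list = field(default_factory=list)


def build_ensemble(
    members, env: xr.Dataset, tss_min: float = TSS_MIN
) -> EnsembleProjection | None:
    """Average the binarized maps of retained members of one species.

    Members with cross-validated TSS below ``tss_min`` are dropped; with no
    retained member the species is excluded (returns None).  Cells missing
    any predictor of any retained member are NaN.
    """
    members = list(members)
    retained = [m for m in members if m.tss is not None and m.tss >= tss_min]
    if not retained:
        return None
    maps = [project_member(m, env) for m in retained]
    stack = xr.concat(maps, dim="member")
    mean = stack.mean(dim="member", skipna=False)
    return EnsembleProjection(
        species_id=retained[0].species_id,
        data=mean,
        n_members=len(retained),
        member_tss=[m.tss for m in retained],
    )
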