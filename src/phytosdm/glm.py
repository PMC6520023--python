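"""Weighted binomial GLM via IRLS, sized for the pipeline's inner loop.

Member fitting runs tens of thousands of small logistic regressions
(stepwise AIC inside 4-fold cross-validation for every predictor set of every
species), where general-purpose model frameworks spend most of their time on
per-fit bookkeeping.  This module solves exactly the statsmodels
``GLM(Binomial, freq_weights)`` problem — same deviance, log-likelihood and
AIC — with plain numpy; the equivalence is pinned by a unit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LogisticFit:
    coef: np.ndarray        # aligned with design columns, intercept first
    deviance: float
    null_deviance: float
    loglik: float
    aic: float
    n: int                  # number of rows
    converged: bool

    @property
    def df_model(self) -> int:
        return self.coef.size


def _loglik(y, eta, w):
    # sum w * (y*eta - log(1 + exp(eta))), stable for large |eta|;
    # softplus written out: logaddexp is several times slower here
    softplus = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return float(np.dot(w, y * eta - softplus))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-7,
    beta0: np.ndarray | None = None,
) -> LogisticFit:
    """Fit a weighted logistic regression; ``X`` must include the intercept.

    ``weights`` are frequency/case weights (e.g. background rows downweighted
    to balance classes).  IRLS with a tiny ridge on the normal equations for
    numerical safety and step-halving on deviance increases; ``beta0`` warm-
    starts the iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    wy = float(np.sum(w * y))

    if beta0 is not None and beta0.size == p:
        beta = beta0.astype(float).copy()
    else:
        beta = np.zeros(p)
        ybar = min(max(wy / wsum, 1e-10), 1 - 1e-10)
        beta[0] = np.log(ybar / (1 - ybar))  # intercept-only start

    eta = np.clip(X @ beta, -35, 35)
    ll = _loglik(y, eta, w)
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        wls = np.maximum(w * mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-10)
        XtW = X.T * wls
        A = XtW @ X
        A.flat[:: p + 1] += 1e-10
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        step = 1.0
        for _half in range(12):
            bn = beta + step * (beta_new - beta)
            eta_n = np.clip(X @ bn, -35, 35)
            ll_n = _loglik(y, eta_n, w)
            if np.isfinite(ll_n) and ll_n >= ll - 1e-8:
                break
            step *= 0.5
        delta = abs(ll_n - ll)
        beta, eta, ll = bn, eta_n, ll_n
        if delta < tol * (abs(ll) + 0.1):
            converged = True
            break

    mu0 = min(max(wy / wsum, 1e-12), 1 - 1e-12)
    eta0 = np.log(mu0 / (1 - mu0))
    null_ll = float(np.sum(w * (y * eta0 - np.logaddexp(0.0, eta0))))
    return LogisticFit(
        coef=beta,
        deviance=float(-2.0 * ll),
        null_deviance=float(-2.0 * null_ll),
        loglik=ll,
        aic=float(-2.0 * ll + 2.0 * p),
        n=n,
        converged=converged,
    )


def predict_logistic(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(np.asarray(X, float) @ coef, -35, 35)
    return 1.0 / (1.0 + np.exp(-eta))


def stepwise_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    start: str = "null",
    max_steps: int = 30,
):
    """Bidirectional AIC stepwise selection over the columns of ``X``.

    Column 0 (intercept) is always kept.  Starting from the intercept-only
    model (or the full model with ``start="full"``), each step takes the
    single add-or-drop move that most improves AIC, stopping when no move
    helps.  Candidate fits are warm-started from the current model's
    coefficients and results are cached per subset, so each subset is fitted
    at most once.  Returns ``(selected_indices, fit)`` where
    ``selected_indices`` always begins with 0.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    current = frozenset(range(1, p)) if start == "full" else frozenset()
    cache: dict = {}

    def fit_subset(cols, warm=None):
        if cols in cache:
            return cache[cols]
        idx = [0] + sorted(cols)
        b0 = None
        if warm is not None:
            warm_idx, warm_coef = warm
            lookup = dict(zip(warm_idx, warm_coef))
            b0 = np.array([lookup.get(j, 0.0) for j in idx])
        fit = fit_logistic(X[:, idx], y, weights, beta0=b0)
        cache[cols] = (idx, fit)
        return idx, fit

    idx, best = fit_subset(current)
    for _ in range(max_steps):
        warm = (idx, best.coef)
        best_move = None
        for j in range(1, p):
            trial = current - {j} if j in current else current | {j}
            t_idx, t_fit = fit_subset(trial, warm)
            if t_fit.aic < best.aic - 1e-9 and (
                best_move is None or t_fit.aic < best_move[2].aic
            ):
                best_move = (trial, t_idx, t_fit)
        if best_move is None:
            break
        current, idx, best = best_move
    return idx, best
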