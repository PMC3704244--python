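"""Penalized-regression baselines: lasso and elastic net.

All loci enter one penalized GLM jointly; covariates are adjustment terms
and stay unpenalized.  The regularization strength is chosen at the
minimal k-fold cross-validation error, and the loci with nonzero ancestry
coefficients at that strength are the selected set.

For the gaussian family the unpenalized covariates are handled exactly by
Frisch-Waugh residualization: profiling the covariate coefficients out of
the penalized least-squares objective leaves a lasso/elastic-net problem in
the residualized trait and dosages, which scikit-learn's coordinate descent
solves on its path of lambdas.  Dosage columns are standardized before
penalization and coefficients mapped back for reporting.

For binomial traits no installed coordinate-descent solver supports
per-feature penalties, so the fit goes through statsmodels'
``GLM.fit_regularized`` with a per-parameter alpha vector (zero on the
intercept and covariates) and a hand-rolled deviance CV over a lambda grid;
this route is exact but slow and intended for modest panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

from .ancestry_sim import AncestryPanel

__all__ = ["PenalizedScanResult", "penalized_scan"]

ENET_L1_RATIO = 0.5


@dataclass
class PenalizedScanResult:
    method: str
    selected: list
    coef: np.ndarray
    alpha: float
    k_folds: int
    seed: int | None = None


def _residualize(y, S, E):
    I = y.shape[0]
    W = np.column_stack([np.ones(I)] + ([E] if E is not None and E.size else []))
    Q, _ = np.linalg.qr(W)
    proj = lambda v: v - Q @ (Q.T @ v)
    return proj(y), S - Q @ (Q.T @ S)


def penalized_scan(panel, y, E=None, method: str = "lasso",
                   family: str = "gaussian", k_folds: int = 10,
                   seed: int | None = None, standardize: bool = True,
                   n_alphas: int = 100) -> PenalizedScanResult:
    """CV-min penalized scan over all loci jointly.

    ``panel`` may be an AncestryPanel (its point dosage matrix is used) or a
    raw (I, J) dosage array.  ``y`` may be a TraitVector or array.
    """
    if method not in ("lasso", "enet"):
        raise ValueError("method must be 'lasso' or 'enet'")
    S = panel.dosage if isinstance(panel, AncestryPanel) else np.asarray(panel)
    S = S.astype(float)
    yv = np.asarray(getattr(y, "values", y), dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("constant trait: cross-validation is degenerate")
    if E is not None:
        E = np.asarray(E, dtype=float)
        if E.ndim == 1:
            E = E.reshape(-1, 1)

    if family == "gaussian":
        return _gaussian_scan(S, yv, E, method, k_folds, seed, standardize,
                              n_alphas)
    if family == "binomial":
        return _binomial_scan(S, yv, E, method, k_folds, seed, standardize)
    raise ValueError(f"unsupported family {family!r}")


def _gaussian_scan(S, y, E, method, k_folds, seed, standardize, n_alphas):
    yt, St = _residualize(y, S, E)
    scale = St.std(axis=0)
    scale[scale == 0] = 1.0
    Z = St / scale if standardize else St
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    if method == "lasso":
        model = LassoCV(cv=cv, alphas=n_alphas, fit_intercept=False,
                        max_iter=5000)
    else:
        model = ElasticNetCV(cv=cv, l1_ratio=ENET_L1_RATIO, alphas=n_alphas,
                             fit_intercept=False, max_iter=5000)
    model.fit(Z, yt)
    coef = model.coef_ / (scale if standardize else 1.0)
    selected = np.flatnonzero(model.coef_ != 0.0).tolist()
    return PenalizedScanResult(method=method, selected=selected, coef=coef,
                               alpha=float(model.alpha_), k_folds=k_folds,
                               seed=seed)


def _binomial_scan(S, y, E, method, k_folds, seed, standardize):
    import statsmodels.api as sm

    I, J = S.shape
    scale = S.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (S - S.mean(axis=0)) / scale if standardize else S
    q = 0 if E is None else E.shape[1]
    X = np.column_stack([np.ones(I), Z] + ([E] if q else []))
    l1_wt = 1.0 if method == "lasso" else ENET_L1_RATIO

    # lambda grid from the unpenalized-score lambda_max downward
    p0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    lam_max = np.max(np.abs(Z.T @ (y - p0))) / I
    lambdas = lam_max * np.logspace(0, -3, 25)

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(I) % k_folds
    dev = np.zeros(len(lambdas))
    for k in range(k_folds):
        tr, te = fold_id != k, fold_id == k
        for li, lam in enumerate(lambdas):
            alpha = np.concatenate([[0.0], np.full(J, lam), np.zeros(q)])
            fit = sm.GLM(y[tr], X[tr], family=sm.families.Binomial()
                         ).fit_regularized(method="elastic_net", alpha=alpha,
                                           L1_wt=l1_wt, maxiter=200)
            eta = np.clip(X[te] @ fit.params, -30, 30)
            mu = 1 / (1 + np.exp(-eta))
            dev[li] += -2 * np.sum(y[te] * np.log(mu) + (1 - y[te]) * np.log1p(-mu))
    lam = lambdas[int(np.argmin(dev))]
    alpha = np.concatenate([[0.0], np.full(J, lam), np.zeros(q)])
    fit = sm.GLM(y, X, family=sm.families.Binomial()
                 ).fit_regularized(method="elastic_net", alpha=alpha,
                                   L1_wt=l1_wt, maxiter=500)
    coef_std = np.asarray(fit.params[1:1 + J])
    coef = coef_std / (scale if standardize else 1.0)
    selected = np.flatnonzero(coef_std != 0.0).tolist()
    return PenalizedScanResult(method=method, selected=selected, coef=coef,
                               alpha=float(lam), k_folds=k_folds, seed=seed)
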