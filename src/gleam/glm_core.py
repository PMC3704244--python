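"""Generalized linear model fits with local-ancestry predictors.

The association model regresses a trait on the local-ancestry dosages at one
or more loci plus optional risk covariates:

    gaussian:  y_i = b0 + beta' S_i + alpha' E_i + eps_i,  eps_i ~ N(0, sigma^2)
    binomial:  logit P(y_i = 1) = b0 + beta' S_i + alpha' E_i
    poisson:   log E[y_i]       = b0 + beta' S_i + alpha' E_i

Ancestry columns are centered to mean zero before fitting so that the prior
scale matrix downstream is the (unit-dispersion) covariance of beta-hat.
Fitting is delegated to statsmodels' IRLS; this module re-expresses the
results in the pieces the Bayes-factor machinery consumes: the ancestry
sub-vector of the MLE, the unit-dispersion covariance factor Sigma-hat
(covariance of beta-hat = sigma2_hat * Sigma_hat), and the dispersion.

For the gaussian family the dispersion is the maximum-likelihood estimate
RSS/I by default (the marginal-likelihood plug-in), with an RSS/(I-k)
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TraitVector",
    "DesignMatrix",
    "GLMFit",
    "SeparationError",
    "DegenerateDesignError",
    "build_design",
    "fit_glm",
    "extract_ancestry_block",
]

FAMILIES = ("gaussian", "binomial", "poisson")


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation in a binomial fit.

    Carries the ancestry-column labels so scans can record the locus as
    skipped rather than silently regularizing.
    """

    def __init__(self, message: str, labels=None):
        super().__init__(message)
        self.labels = list(labels) if labels is not None else []


class DegenerateDesignError(ValueError):
    """Design has a constant ancestry column or is rank deficient."""


@dataclass
class TraitVector:
    """Trait observations with their GLM family tag."""

    values: np.ndarray
    family: str = "gaussian"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trait must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait contains missing/non-finite values")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "binomial" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binomial trait values must be 0/1")
        if self.family == "poisson":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("poisson trait values must be non-negative integers")

    def __len__(self):
        return self.values.size


@dataclass
class DesignMatrix:
    """Intercept + centered ancestry block + covariate block, with roles.

    ``X`` stacks [intercept | S (centered) | E]; ``ancestry_idx`` and
    ``covariate_idx`` record column roles.  ``degenerate`` flags a constant
    ancestry column (zero dosage variance at a locus), which downstream
    scans report as a skipped locus.
    """

    X: np.ndarray
    ancestry_idx: np.ndarray
    covariate_idx: np.ndarray
    ancestry_labels: list = field(default_factory=list)
    degenerate: bool = False
    degenerate_labels: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.ancestry_idx.size

    @property
    def S(self) -> np.ndarray:
        return self.X[:, self.ancestry_idx]


@dataclass
class GLMFit:
    """Fitted GLM in the form the Bayes factor consumes.

    ``Sigma_hat`` is the unit-dispersion covariance factor of the ancestry
    coefficients: cov(beta_hat_S) = sigma2_hat * Sigma_hat.  For binomial and
    poisson fits sigma2_hat == 1 and Sigma_hat is the ancestry block of the
    inverse observed information.
    """

    beta_hat_all: np.ndarray
    beta_hat_S: np.ndarray
    Sigma_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    n_obs: int
    family: str
    converged: bool
    ancestry_labels: list = field(default_factory=list)


def build_design(S_block, E=None, center: bool = True, labels=None) -> DesignMatrix:
    """Assemble intercept + ancestry dosages + covariates into a design.

    Parameters
    ----------
    S_block : (I, p) array
        Local-ancestry dosages (0/1/2 copies from the high-risk population).
    E : (I, q) array or None
        Risk covariates; ``None`` or zero columns for an unadjusted model.
    center : bool
        Center each ancestry column to mean zero (the default, and what the
        prior construction assumes).
    """
    S = np.asarray(S_block, dtype=float)
    if S.ndim == 1:
        S = S.reshape(-1, 1)
    I, p = S.shape
    if E is None:
        E = np.empty((I, 0))
    E = np.asarray(E, dtype=float)
    if E.ndim == 1:
        E = E.reshape(-1, 1)
    if E.shape[0] != I:
        raise ValueError(f"row mismatch: S has {I} rows, E has {E.shape[0]}")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(E))):
        raise ValueError("missing/non-finite entries in design inputs")

    labels = list(labels) if labels is not None else [f"S{j}" for j in range(p)]
    if len(labels) != p:
        raise ValueError("labels length must match number of ancestry columns")

    sd = S.std(axis=0)
    degenerate_cols = np.flatnonzero(sd == 0.0)
    if center:
        S = S - S.mean(axis=0)

    X = np.column_stack([np.ones(I), S, E])
    return DesignMatrix(
        X=X,
        ancestry_idx=np.arange(1, 1 + p),
        covariate_idx=np.arange(1 + p, 1 + p + E.shape[1]),
        ancestry_labels=labels,
        degenerate=degenerate_cols.size > 0,
        degenerate_labels=[labels[j] for j in degenerate_cols],
    )


_SM_FAMILY = {
    "gaussian": sm.families.Gaussian,
    "binomial": sm.families.Binomial,
    "poisson": sm.families.Poisson,
}

# guards against an exactly-zero residual variance in noiseless toy data
_SIGMA2_FLOOR = 1e-12


def fit_glm(y: TraitVector, X: DesignMatrix, scale_estimator: str = "ml") -> GLMFit:
    """Fit the GLM and extract the ancestry block of the result.

    ``scale_estimator`` applies to the gaussian family only: ``"ml"`` uses
    RSS/I (default), ``"unbiased"`` RSS/(I - k).
    """
    if X.degenerate:
        raise DegenerateDesignError(
            f"constant ancestry column(s): {X.degenerate_labels}"
        )
    yv = y.values
    if yv.size != X.n_obs:
        raise ValueError("trait and design row counts differ")
    if np.linalg.matrix_rank(X.X) < X.X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")

    model = sm.GLM(yv, X.X, family=_SM_FAMILY[y.family]())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except PerfectSeparationError as exc:  # statsmodels detects collapse
        raise SeparationError(str(exc), labels=X.ancestry_labels) from exc

    params = np.asarray(res.params)
    mu = np.asarray(res.fittedvalues)
    converged = bool(getattr(res, "converged", True))

    if y.family == "binomial":
        # quasi-complete separation: fitted probabilities pinned at 0/1 with
        # runaway coefficients; statsmodels may not raise on its own
        eta = X.X @ params
        if np.max(np.abs(eta)) > 30 and np.max(np.abs(params)) > 15:
            raise SeparationError(
                "fitted probabilities numerically 0/1 (separation)",
                labels=X.ancestry_labels,
            )
        score = X.X.T @ (yv - mu)
        if not converged or np.max(np.abs(score)) > 1e-6:
            raise RuntimeError("IRLS failed to converge")

    if y.family == "gaussian":
        rss = float(np.sum((yv - mu) ** 2))
        I, k = X.n_obs, X.X.shape[1]
        sigma2 = rss / I if scale_estimator == "ml" else rss / max(I - k, 1)
        sigma2 = max(sigma2, _SIGMA2_FLOOR)
        loglik = -0.5 * I * (np.log(2 * np.pi * sigma2) + rss / (I * sigma2))
    else:
        sigma2 = 1.0
        loglik = float(res.llf)

    # unit-dispersion covariance factor (X'WX)^-1; ancestry sub-block
    ncov = np.asarray(res.normalized_cov_params)
    aidx = X.ancestry_idx
    Sigma = ncov[np.ix_(aidx, aidx)]
    Sigma = 0.5 * (Sigma + Sigma.T)

    return GLMFit(
        beta_hat_all=params,
        beta_hat_S=params[aidx].copy(),
        Sigma_hat=Sigma,
        sigma2_hat=float(sigma2),
        loglik=float(loglik),
        n_obs=X.n_obs,
        family=y.family,
        converged=converged,
        ancestry_labels=list(X.ancestry_labels),
    )


def extract_ancestry_block(fit: GLMFit):
    """Return (beta_hat_S, Sigma_hat sub-block, sigma2_hat) from a fit.

    Covariate adjustment happens through the joint fit: Sigma_hat is the
    ancestry block of the full inverse information, not a residualized
    recomputation.
    """
    if not fit.converged:
        raise RuntimeError("cannot extract ancestry block from a failed fit")
    return fit.beta_hat_S, fit.Sigma_hat, fit.sigma2_hat
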