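"""Quadratic normal moment (QNM) prior for ancestry effect sizes.

A non-local prior on the p-vector of ancestry effects beta under H1:

    f_QNM(beta; tau, sigma2, Sigma)
        = [beta' Sigma^-1 beta / (I tau sigma2 p)] * N_p(beta; 0, I tau sigma2 Sigma)

where Sigma is the unit-dispersion covariance factor of the least-squares /
IRLS estimate of beta (so sigma2*Sigma is its sampling covariance), I the
number of subjects and tau the prior dispersion multiplier.  The quadratic
factor vanishes at beta = 0, separating the alternative from the null; the
normalizer is exact because E[beta' Sigma^-1 beta] = p * I tau sigma2 under
the embedded normal.

With Sigma = (S'S)^-1 the prior scale at a locus shrinks as the dosage
variance grows, i.e. loci with a higher high-risk ancestry proportion carry
larger prior effect magnitudes — the admixture prior knowledge the method
encodes.

Sampling uses the exact radial decomposition: writing beta =
sqrt(v) L z with v = I tau sigma2 and Sigma = L L', the density of z is
spherical with squared radius distributed chi-square with p + 2 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2

__all__ = ["QNMParams", "qnm_logdensity", "qnm_density", "qnm_sample", "qnm_mode_1d"]


@dataclass
class QNMParams:
    """Parameters of the QNM prior (all strictly positive; Sigma PD)."""

    tau: float
    sigma2: float
    Sigma: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if self.tau <= 0 or self.sigma2 <= 0 or self.n_subjects <= 0:
            raise ValueError("tau, sigma2 and n_subjects must be positive")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        try:
            self._chol = linalg.cholesky(self.Sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]

    @property
    def v(self) -> float:
        """Scale of the embedded normal: I * tau * sigma2."""
        return self.n_subjects * self.tau * self.sigma2


def qnm_logdensity(beta, params: QNMParams):
    """Log density of the QNM prior; -inf at beta = 0.

    Accepts a single p-vector or an (n, p) batch.
    """
    b = np.asarray(beta, dtype=float)
    single = b.ndim == 1
    b = np.atleast_2d(b)
    if b.shape[1] != params.p:
        raise ValueError(f"beta must have length p={params.p}")
    v, p, L = params.v, params.p, params._chol
    # z = L^-1 beta: beta'Sigma^-1 beta = |z|^2
    z = linalg.solve_triangular(L, b.T, lower=True).T
    q = np.sum(z * z, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lognorm = -0.5 * (p * np.log(2 * np.pi * v) + logdet)
    with np.errstate(divide="ignore"):
        out = np.log(q) - np.log(v * p) + lognorm - q / (2 * v)
    return out[0] if single else out


def qnm_density(beta, params: QNMParams):
    """Density of the QNM prior (0 at beta = 0)."""
    ld = qnm_logdensity(beta, params)
    return np.exp(ld)


def qnm_mode_1d(params: QNMParams) -> float:
    """Magnitude of the two modes for p = 1: sqrt(2 * I tau sigma2 * Sigma)."""
    if params.p != 1:
        raise ValueError("mode formula applies to p = 1")
    return float(np.sqrt(2.0 * params.v * params.Sigma[0, 0]))


def qnm_sample(n: int, params: QNMParams, seed=None) -> np.ndarray:
    """Draw n samples from the QNM prior (exact, no rejection).

    The spherical representation makes the squared radius of the whitened
    effect chi-square with p + 2 df; directions are uniform on the sphere.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p, v, L = params.p, params.v, params._chol
    r2 = chi2.ppf(rng.uniform(size=n), df=p + 2)
    u = rng.standard_normal((n, p))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    z = np.sqrt(r2)[:, None] * u
    return np.sqrt(v) * z @ L.T
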