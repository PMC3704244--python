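"""Two-ancestry hidden Markov model for local-ancestry imputation.

A conventional admixture HMM over unphased AIM genotypes.  The hidden state
at each locus is the local-ancestry dosage d in {0, 1, 2} (copies from
population 1, the high-risk population).  Each of the two haplotypes
switches ancestry along the genetic map with probability
1 - exp(-g d_cM / 100) per interval, refreshing to Bernoulli(mu) where mu is
the subject's admixture proportion; the dosage transition matrix is the
convolution of the two independent haplotype chains.  Emissions assume HWE
within ancestry: with d haplotypes from population 1, the genotype is the
sum of d Bernoulli(f1) and 2 - d Bernoulli(f2) allele draws, where f1/f2
are the reference-allele frequencies in the two ancestral populations
(clamped away from 0/1 to keep every observation possible).

Forward-backward runs in log space (stable for 10^4+ loci).  Multiple
imputation uses joint backward sampling of whole state paths, which
preserves the along-chromosome ancestry correlation that per-locus
independent draws would destroy — the property multilocus mapping relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

__all__ = [
    "AIMGenotypes",
    "AncestralFreqs",
    "HMMParams",
    "ImputationSet",
    "hmm_posteriors",
    "sample_imputations",
    "estimate_global_ancestry",
]

FREQ_CLAMP = 1e-3
MU_BOUNDS = (0.001, 0.999)


@dataclass
class AIMGenotypes:
    """Reference-allele dosages (0/1/2) at AIMs with a genetic map."""

    dosage: np.ndarray  # (I, J)
    cM: np.ndarray
    chrom: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        self.cM = np.asarray(self.cM, dtype=float)
        if not np.all(np.isin(self.dosage, (0, 1, 2))):
            raise ValueError("genotype dosages must be 0/1/2")
        if self.chrom is None:
            self.chrom = np.ones(self.cM.size, dtype=int)
        same = np.asarray(self.chrom)[1:] == np.asarray(self.chrom)[:-1]
        if np.any(np.diff(self.cM)[same] < 0):
            raise ValueError("map must be sorted within chromosomes")


@dataclass
class AncestralFreqs:
    """Per-locus reference-allele frequencies in the two populations."""

    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self):
        self.f1 = np.clip(np.asarray(self.f1, dtype=float), FREQ_CLAMP, 1 - FREQ_CLAMP)
        self.f2 = np.clip(np.asarray(self.f2, dtype=float), FREQ_CLAMP, 1 - FREQ_CLAMP)


@dataclass
class HMMParams:
    """Admixture proportion(s) mu and generations-since-admixture g."""

    mu: float | np.ndarray = 0.8
    g: float = 6.0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        if np.any((mu <= 0) | (mu >= 1)) or self.g <= 0:
            raise ValueError("mu in (0,1) and g > 0 required")


@dataclass
class ImputationSet:
    """M sampled dosage panels plus the per-locus posterior mean dosage."""

    draws: np.ndarray  # (M, I, J) int8
    posterior_mean: np.ndarray  # (I, J)


def _emission_logprobs(genos: AIMGenotypes, freqs: AncestralFreqs) -> np.ndarray:
    """log P(genotype | dosage state) as an (I, J, 3) array."""
    f1, f2 = freqs.f1, freqs.f2  # (J,)
    # P(g | d): d haplotypes Bernoulli(f1), 2-d Bernoulli(f2)
    probs = np.empty((3, 3, f1.size))  # (d, g, J)
    for d in range(3):
        hap_p = [f1 if h < d else f2 for h in range(2)]
        p00 = (1 - hap_p[0]) * (1 - hap_p[1])
        p11 = hap_p[0] * hap_p[1]
        probs[d, 0] = p00
        probs[d, 2] = p11
        probs[d, 1] = 1 - p00 - p11
    G = genos.dosage  # (I, J)
    J = f1.size
    out = np.empty((G.shape[0], J, 3))
    for d in range(3):
        out[:, :, d] = np.log(probs[d, G, np.arange(J)[None, :]])
    return out


def _hap_transition(e: float, mu: float) -> np.ndarray:
    """2x2 haplotype ancestry transition (state 1 = population 1)."""
    return np.array([
        [e + (1 - e) * (1 - mu), (1 - e) * mu],
        [(1 - e) * (1 - mu), e + (1 - e) * mu],
    ])


def _dosage_transitions(genos: AIMGenotypes, params: HMMParams) -> np.ndarray:
    """(J-1, 3, 3) dosage transition matrices along the map."""
    d_cM = np.diff(genos.cM)
    same = np.asarray(genos.chrom)[1:] == np.asarray(genos.chrom)[:-1]
    mu = float(np.mean(params.mu))
    mats = np.empty((d_cM.size, 3, 3))
    for j, (d, s) in enumerate(zip(d_cM, same)):
        e = np.exp(-params.g * d / 100.0) if s else 0.0
        Th = _hap_transition(e, mu)
        # dosage k -> k': convolution of the two haplotype chains
        M = np.zeros((3, 3))
        for k in range(3):
            rows = [Th[1] if h < k else Th[0] for h in range(2)]
            conv = np.outer(rows[0], rows[1])
            M[k, 0] = conv[0, 0]
            M[k, 1] = conv[0, 1] + conv[1, 0]
            M[k, 2] = conv[1, 1]
        mats[j] = M
    return mats


def _prior(mu: float) -> np.ndarray:
    return np.array([(1 - mu) ** 2, 2 * mu * (1 - mu), mu**2])


def _forward(logem, logT, logpi):
    I, J, _ = logem.shape
    alpha = np.empty((I, J, 3))
    alpha[:, 0] = logpi[None, :] + logem[:, 0]
    for j in range(1, J):
        # logsumexp over previous state
        prev = alpha[:, j - 1][:, :, None] + logT[j - 1][None, :, :]
        alpha[:, j] = logsumexp(prev, axis=1) + logem[:, j]
    return alpha


def hmm_posteriors(genos: AIMGenotypes, freqs: AncestralFreqs, params: HMMParams
                   ) -> np.ndarray:
    """Per-subject, per-locus posterior over dosage states, (I, J, 3).

    Forward-backward in log space; rows sum to 1.
    """
    if genos.cM.size != freqs.f1.size:
        raise ValueError("genotypes and frequencies are misaligned")
    logem = _emission_logprobs(genos, freqs)
    with np.errstate(divide="ignore"):
        logT = np.log(_dosage_transitions(genos, params))
        logpi = np.log(_prior(float(np.mean(params.mu))))
    I, J, _ = logem.shape
    alpha = _forward(logem, logT, logpi)
    beta = np.zeros((I, J, 3))
    for j in range(J - 2, -1, -1):
        nxt = logT[j][None, :, :] + (logem[:, j + 1] + beta[:, j + 1])[:, None, :]
        beta[:, j] = logsumexp(nxt, axis=2)
    post = alpha + beta
    post -= logsumexp(post, axis=2, keepdims=True)
    return np.exp(post)


def loglikelihood(genos: AIMGenotypes, freqs: AncestralFreqs, params: HMMParams
                  ) -> np.ndarray:
    """Per-subject marginal log-likelihood (finite even for very long maps)."""
    logem = _emission_logprobs(genos, freqs)
    with np.errstate(divide="ignore"):
        logT = np.log(_dosage_transitions(genos, params))
        logpi = np.log(_prior(float(np.mean(params.mu))))
    alpha = _forward(logem, logT, logpi)
    return logsumexp(alpha[:, -1], axis=1)


def sample_imputations(genos: AIMGenotypes, freqs: AncestralFreqs,
                       params: HMMParams, M: int, seed=None) -> ImputationSet:
    """Joint backward sampling of M whole dosage paths per subject."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    logem = _emission_logprobs(genos, freqs)
    with np.errstate(divide="ignore"):
        logT = np.log(_dosage_transitions(genos, params))
        logpi = np.log(_prior(float(np.mean(params.mu))))
    I, J, _ = logem.shape
    alpha = _forward(logem, logT, logpi)

    draws = np.empty((M, I, J), dtype=np.int8)
    for m in range(M):
        # sample the last state, then walk backwards
        pl = alpha[:, -1]
        pl = np.exp(pl - logsumexp(pl, axis=1, keepdims=True))
        state = _sample_rows(pl, rng)
        draws[m, :, -1] = state
        for j in range(J - 2, -1, -1):
            logp = alpha[:, j] + logT[j][:, state].T
            p = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
            state = _sample_rows(p, rng)
            draws[m, :, j] = state
    post = hmm_posteriors(genos, freqs, params)
    pm = np.einsum("ijd,d->ij", post, np.arange(3.0))
    return ImputationSet(draws=draws, posterior_mean=pm)


def _sample_rows(p: np.ndarray, rng) -> np.ndarray:
    """One categorical draw per row of a (n, 3) probability matrix."""
    u = rng.random(p.shape[0])
    return (u[:, None] > np.cumsum(p, axis=1)[:, :2]).sum(axis=1)


def estimate_global_ancestry(genos: AIMGenotypes, freqs: AncestralFreqs,
                             min_informative: int = 10) -> np.ndarray:
    """Per-subject ML admixture proportion under locus independence.

    Maximizes prod_j sum_d Binom(2, mu)(d) P(g_j | d) over mu in (0.001,
    0.999) separately per subject; invariant to locus order.
    """
    informative = np.abs(freqs.f1 - freqs.f2) > 1e-6
    if informative.sum() < min_informative:
        raise ValueError("too few informative AIMs to estimate ancestry")
    logem = _emission_logprobs(genos, freqs)[:, informative, :]
    I = logem.shape[0]
    mu_hat = np.empty(I)
    for i in range(I):
        em = logem[i]  # (Jinf, 3)

        def nll(mu):
            pri = np.log(_prior(mu))
            return -float(np.sum(logsumexp(em + pri[None, :], axis=1)))

        res = minimize_scalar(nll, bounds=MU_BOUNDS, method="bounded",
                              options={"xatol": 1e-6})
        mu_hat[i] = float(np.clip(res.x, *MU_BOUNDS))
    return mu_hat
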