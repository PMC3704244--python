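import itertools

import numpy as np
import pytest

from gleam.local_ancestry_hmm import (
    AIMGenotypes,
    AncestralFreqs,
    HMMParams,
    _dosage_transitions,
    _emission_logprobs,
    _prior,
    estimate_global_ancestry,
    hmm_posteriors,
    loglikelihood,
    sample_imputations,
)


def _toy_chain(rng, I=4, J=5, informative=True, mu=0.8, g=6.0, spacing=5.0):
    f1 = np.full(J, 0.9 if informative else 0.5)
    f2 = np.full(J, 0.1 if informative else 0.5)
    freqs = AncestralFreqs(f1=f1, f2=f2)
    genos = AIMGenotypes(dosage=rng.integers(0, 3, size=(I, J)),
                         cM=np.arange(J) * spacing)
    return genos, freqs, HMMParams(mu=mu, g=g)


def _brute_force_posteriors(genos, freqs, params):
    """Enumerate all 3^J dosage paths; the oracle forward-backward must match."""
    logem = _emission_logprobs(genos, freqs)
    with np.errstate(divide="ignore"):
        logT = np.log(_dosage_transitions(genos, params))
        logpi = np.log(_prior(float(np.mean(params.mu))))
    I, J, _ = logem.shape
    post = np.zeros((I, J, 3))
    for i in range(I):
        weights = {}
        for path in itertools.product(range(3), repeat=J):
            lp = logpi[path[0]] + logem[i, 0, path[0]]
            for j in range(1, J):
                lp += logT[j - 1][path[j - 1], path[j]] + logem[i, j, path[j]]
            weights[path] = lp
        mx = max(weights.values())
        Z = sum(np.exp(v - mx) for v in weights.values())
        for path, lp in weights.items():
            w = np.exp(lp - mx) / Z
            for j, d in enumerate(path):
                post[i, j, d] += w
    return post


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        genos, freqs, params = _toy_chain(rng, I=3, J=5)
        post = hmm_posteriors(genos, freqs, params)
        brute = _brute_force_posteriors(genos, freqs, params)
        assert np.max(np.abs(post - brute)) < 1e-10

    def test_posteriors_sum_to_one(self, rng):
        genos, freqs, params = _toy_chain(rng, I=5, J=8)
        post = hmm_posteriors(genos, freqs, params)
        np.testing.assert_allclose(post.sum(axis=2), 1.0, atol=1e-12)

    def test_uninformative_markers_return_the_admixture_prior(self, rng):
        genos, freqs, params = _toy_chain(rng, informative=False, mu=0.7)
        post = hmm_posteriors(genos, freqs, params)
        np.testing.assert_allclose(post, np.broadcast_to(_prior(0.7), post.shape),
                                   atol=1e-12)

    def test_informative_markers_recover_simulated_ancestry(self, rng):
        # simulate a dosage path, emit near-deterministic genotypes, decode
        from gleam.ancestry_sim import sim_chromosome

        J, I = 12, 40
        cM = np.arange(J) * 2.0
        panel = sim_chromosome(cM, np.full(J, 0.8), g=6.0, I=I, seed=rng)
        truth = panel.dosage
        f1, f2 = np.full(J, 0.999), np.full(J, 0.001)
        geno = truth  # with these frequencies genotype ~= ancestry dosage
        genos = AIMGenotypes(dosage=geno, cM=cM)
        post = hmm_posteriors(genos, AncestralFreqs(f1=f1, f2=f2),
                              HMMParams(mu=0.8, g=6.0))
        picked = post[np.arange(I)[:, None], np.arange(J)[None, :], truth]
        assert np.mean(picked > 0.99) > 0.95

    def test_long_chain_stays_finite(self):
        rng = np.random.default_rng(0)
        genos, freqs, params = _toy_chain(rng, I=1, J=10_000, spacing=0.5)
        ll = loglikelihood(genos, freqs, params)
        assert np.all(np.isfinite(ll))


class TestSampling:
    def test_sampled_marginals_match_posteriors(self, rng):
        genos, freqs, params = _toy_chain(rng, I=3, J=4)
        M = 4000
        imp = sample_imputations(genos, freqs, params, M=M, seed=1)
        post = hmm_posteriors(genos, freqs, params)
        for d in range(3):
            freq = (imp.draws == d).mean(axis=0)
            se = np.sqrt(post[..., d] * (1 - post[..., d]) / M) + 1e-3
            assert np.all(np.abs(freq - post[..., d]) < 4 * se)

    def test_adjacent_loci_keep_positive_ancestry_correlation(self, rng):
        # tight linkage + uninformative markers: correlation comes only from
        # joint path sampling, so per-locus independent draws would fail this
        genos, freqs, params = _toy_chain(rng, I=300, J=2, informative=False,
                                          spacing=0.2)
        imp = sample_imputations(genos, freqs, params, M=30, seed=2)
        flat = imp.draws.reshape(-1, 2).astype(float)
        r = np.corrcoef(flat.T)[0, 1]
        assert r > 0.5

    def test_fixed_seed_reproduces_draws(self, rng):
        genos, freqs, params = _toy_chain(rng)
        a = sample_imputations(genos, freqs, params, M=3, seed=5).draws
        b = sample_imputations(genos, freqs, params, M=3, seed=5).draws
        np.testing.assert_array_equal(a, b)

    def test_posterior_mean_dosage_in_range(self, rng):
        genos, freqs, params = _toy_chain(rng)
        imp = sample_imputations(genos, freqs, params, M=2, seed=6)
        assert np.all((imp.posterior_mean >= 0) & (imp.posterior_mean <= 2))


class TestGlobalAncestry:
    def _simulate_subject(self, rng, mu, J=1000):
        anc = rng.binomial(2, mu, size=J)
        f1, f2 = np.full(J, 0.9), np.full(J, 0.1)
        # allele draws per haplotype ancestry
        g = rng.binomial(anc, 0.9) + rng.binomial(2 - anc, 0.1)
        return AIMGenotypes(dosage=g.reshape(1, -1), cM=np.arange(J) * 1.0), \
            AncestralFreqs(f1=f1, f2=f2)

    def test_recovers_simulated_admixture_proportion(self, rng):
        genos, freqs = self._simulate_subject(rng, mu=0.8)
        mu_hat = estimate_global_ancestry(genos, freqs)
        assert abs(mu_hat[0] - 0.8) < 0.05

    def test_boundary_genotypes_are_clamped(self):
        J = 50
        genos = AIMGenotypes(dosage=np.full((1, J), 2), cM=np.arange(J) * 1.0)
        freqs = AncestralFreqs(f1=np.full(J, 0.95), f2=np.full(J, 0.05))
        mu_hat = estimate_global_ancestry(genos, freqs)
        assert 0.9 < mu_hat[0] <= 0.999

    def test_invariant_to_locus_permutation(self, rng):
        genos, freqs = self._simulate_subject(rng, mu=0.7, J=200)
        perm = rng.permutation(200)
        genos_p = AIMGenotypes(dosage=genos.dosage[:, perm], cM=np.arange(200) * 1.0)
        freqs_p = AncestralFreqs(f1=freqs.f1[perm], f2=freqs.f2[perm])
        a = estimate_global_ancestry(genos, freqs)[0]
        b = estimate_global_ancestry(genos_p, freqs_p)[0]
        assert a == pytest.approx(b, abs=1e-6)

    def test_uninformative_panel_rejected(self):
        genos = AIMGenotypes(dosage=np.ones((1, 20), dtype=int),
                             cM=np.arange(20) * 1.0)
        freqs = AncestralFreqs(f1=np.full(20, 0.5), f2=np.full(20, 0.5))
        with pytest.raises(ValueError, match="informative"):
            estimate_global_ancestry(genos, freqs)
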