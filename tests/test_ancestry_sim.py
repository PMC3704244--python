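import numpy as np
import pytest
from scipy.stats import chisquare, norm

from gleam.ancestry_sim import (
    SimDesign,
    artificial_chromosome_map,
    classify_regions,
    dichotomize_extremes,
    map_allele_freq,
    null_design,
    run_experiment,
    sim_chromosome,
    sim_correlated_pair,
    sim_hwe_panel,
    sim_traits,
    two_locus_design,
)
from gleam.glm_core import TraitVector, build_design, fit_glm


class TestMapAlleleFreq:
    def test_uniform_prior_reduces_to_sample_frequency(self):
        assert map_allele_freq(2000, I=1000) == pytest.approx(1.0)
        assert map_allele_freq(1600, I=1000) == pytest.approx(0.8)

    def test_beta_prior_shrinks_boundary_counts(self):
        assert map_allele_freq(0, I=5, prior_a=2, prior_b=2) == pytest.approx(1 / 12)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            map_allele_freq(2001, I=1000)


class TestHWEPanel:
    def test_fixation_gives_all_two_copies(self):
        panel = sim_hwe_panel([1.0, 1.0], I=20, seed=0)
        assert np.all(panel.dosage == 2)

    def test_genotype_frequencies_within_monte_carlo_error(self):
        I = 100_000
        panel = sim_hwe_panel([0.8], I=I, seed=1)
        freqs = np.bincount(panel.dosage[:, 0], minlength=3) / I
        expected = np.array([0.04, 0.32, 0.64])
        se = np.sqrt(expected * (1 - expected) / I)
        assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_fixed_seed_is_bit_identical(self):
        a = sim_hwe_panel([0.7, 0.8], I=50, seed=9)
        b = sim_hwe_panel([0.7, 0.8], I=50, seed=9)
        np.testing.assert_array_equal(a.dosage, b.dosage)


class TestCorrelatedPair:
    def test_threshold_constants_at_p08(self):
        # construction constants: C0 = Phi^-1(0.04), C1 = Phi^-1(0.36)
        assert norm.ppf((1 - 0.8) ** 2) == pytest.approx(norm.ppf(0.04))
        assert norm.ppf(1 - 0.8**2) == pytest.approx(norm.ppf(0.36))

    def test_marginals_are_exactly_hwe(self):
        I = 100_000
        s1, s2 = sim_correlated_pair(0.8, rho=0.75, I=I, seed=2)
        expected = I * np.array([0.04, 0.32, 0.64])
        for s in (s1, s2):
            counts = np.bincount(s, minlength=3)
            assert chisquare(counts, expected).pvalue > 1e-4

    def test_independence_at_zero_latent_correlation(self):
        s1, s2 = sim_correlated_pair(0.8, rho=0.0, I=50_000, seed=3)
        assert abs(np.corrcoef(s1, s2)[0, 1]) < 3 / np.sqrt(50_000)

    def test_correlation_increases_with_rho(self):
        corrs = []
        for rho in (0.25, 0.75):
            s1, s2 = sim_correlated_pair(0.8, rho=rho, I=10_000, seed=4)
            corrs.append(np.corrcoef(s1, s2)[0, 1])
        assert corrs[1] > corrs[0] > 0


class TestChromosome:
    def test_zero_distance_copies_ancestry_exactly(self):
        panel = sim_chromosome([10.0, 10.0], [0.8, 0.8], g=5.0, I=2000, seed=5)
        np.testing.assert_array_equal(panel.dosage[:, 0], panel.dosage[:, 1])

    def test_stationary_ancestry_fraction(self):
        p = 0.8
        panel = sim_chromosome(np.arange(10) * 5.0, np.full(10, p), g=6.0,
                               I=10_000, seed=6)
        frac = panel.dosage.mean() / 2
        se = np.sqrt(p * (1 - p) / (2 * 10_000))
        assert abs(frac - p) < 4 * se

    def test_dosage_correlation_decays_with_distance(self):
        cM = np.arange(12) * 4.0
        acc = np.zeros(11)
        for k in range(30):
            panel = sim_chromosome(cM, np.full(12, 0.8), g=6.0, I=800, seed=100 + k)
            S = panel.dosage.astype(float)
            c = np.corrcoef(S.T)[0, 1:]
            acc += c
        acc /= 30
        assert np.all(np.diff(acc) < 0.02)  # non-increasing up to MC noise
        assert acc[0] > acc[-1] + 0.2

    def test_fidelity_attenuates_correlation_quadratically(self):
        cM = np.array([0.0, 2.0])
        r = {}
        for f in (1.0, 0.5):
            panel = sim_chromosome(cM, [0.8, 0.8], g=1.0, I=60_000, seed=7,
                                   fidelity=f)
            S = panel.dosage.astype(float)
            r[f] = np.corrcoef(S.T)[0, 1]
        assert r[0.5] == pytest.approx(0.25 * r[1.0], abs=0.02)

    def test_non_monotone_map_raises(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            sim_chromosome([0.0, 5.0, 3.0], [0.8] * 3, g=1.0, I=10, seed=8)

    def test_independent_across_chromosome_boundaries(self):
        panel = sim_chromosome([0.0, 0.0], [0.8, 0.8], g=0.1, I=50_000, seed=9,
                               chrom=[1, 2])
        S = panel.dosage.astype(float)
        assert abs(np.corrcoef(S.T)[0, 1]) < 0.02


class TestTraits:
    def test_pure_noise_trait_is_standard_normal(self):
        design = null_design(n_loci=5, n_subjects=20_000)
        panel = sim_hwe_panel(np.full(5, 0.8), 20_000, seed=10)
        y, E = sim_traits(panel, design, seed=11)
        assert abs(np.mean(y.values)) < 0.03
        assert np.var(y.values) == pytest.approx(1.0, abs=0.03)

    def test_effect_is_c_times_ancestry_proportion(self):
        # same seed with and without the effect isolates beta * S exactly
        panel = sim_hwe_panel([0.8817], I=50, seed=12)
        base = SimDesign(family="gaussian", n_subjects=50, n_loci=1,
                         causal_idx=(0,), c=(0.0,), alpha=0.0)
        design = SimDesign(family="gaussian", n_subjects=50, n_loci=1,
                           causal_idx=(0,), c=(0.4,), alpha=0.0)
        y0, _ = sim_traits(panel, base, seed=13)
        y1, _ = sim_traits(panel, design, seed=13)
        diff = y1.values - y0.values
        S = panel.dosage[:, 0].astype(float)
        nz = S > 0
        np.testing.assert_allclose(diff[nz] / S[nz], 0.4 * 0.8817, rtol=1e-12)

    def test_binomial_effect_recovered_by_refit(self, rng):
        I = 4000
        panel = sim_hwe_panel([0.85], I, seed=14)
        design = SimDesign(family="binomial", n_subjects=I, n_loci=1,
                           causal_idx=(0,), c=(0.6,), alpha=0.0)
        y, E = sim_traits(panel, design, seed=15)
        fit = fit_glm(y, build_design(panel.dosage[:, 0].astype(float)))
        beta_true = 0.6 * 0.85
        se = np.sqrt(fit.Sigma_hat[0, 0])
        assert abs(fit.beta_hat_S[0] - beta_true) < 3 * se


class TestDichotomize:
    def test_extreme_quintiles_of_a_ramp(self):
        labels, mask = dichotomize_extremes(np.arange(1.0, 11.0), q=0.2)
        assert set(np.flatnonzero(mask & (labels == 1))) == {8, 9}
        assert set(np.flatnonzero(mask & (labels == 0))) == {0, 1}
        assert mask.sum() == 4

    def test_counts_match_the_rule(self, rng):
        labels, mask = dichotomize_extremes(rng.standard_normal(1000), q=0.2)
        assert (labels[mask] == 1).sum() == 200
        assert (labels[mask] == 0).sum() == 200

    def test_constant_trait_raises(self):
        with pytest.raises(ValueError):
            dichotomize_extremes(np.ones(10), q=0.2)


class TestRegions:
    def test_linkage_equilibrium_panel_has_empty_flanking_regions(self):
        panel = sim_hwe_panel(np.full(40, 0.8), I=5000, seed=16)
        reg = classify_regions(panel, (10, 30))
        assert reg.indices("REG1").size <= 2  # chance exceedances only
        assert reg.indices("LOCUS1").size == 1

    def test_threshold_one_labels_everything_reg3(self):
        panel = sim_hwe_panel(np.full(10, 0.8), I=500, seed=17)
        reg = classify_regions(panel, (2, 7), r_threshold=1.0)
        assert reg.indices("REG1").size == 0 and reg.indices("REG2").size == 0
        assert reg.indices("REG3").size == 8

    def test_labels_partition_all_loci(self):
        panel = sim_hwe_panel(np.full(15, 0.8), I=300, seed=18)
        reg = classify_regions(panel, (3, 9))
        sizes = sum(reg.indices(n).size for n in
                    ("LOCUS1", "LOCUS2", "REG1", "REG2", "REG3"))
        assert sizes == 15

    def test_coincident_causal_loci_raise(self):
        panel = sim_hwe_panel(np.full(5, 0.8), I=100, seed=19)
        with pytest.raises(ValueError):
            classify_regions(panel, (2, 2))

    def test_markov_chromosome_regions_flank_the_causal_loci(self):
        cM, chrom, causal = artificial_chromosome_map()
        rng = np.random.default_rng(20)
        p_a = rng.uniform(0.7, 0.9, size=102)
        panel = sim_chromosome(cM, p_a, g=0.25, I=1000, seed=21, chrom=chrom,
                               fidelity=0.387)
        reg = classify_regions(panel, causal)
        # flanking regions live on the causal locus's own piece
        assert np.all(reg.indices("REG1") < 51)
        assert np.all(reg.indices("REG2") >= 51)
        assert reg.indices("REG1").size > 20


class TestExperiments:
    def test_zero_replicates_give_empty_table(self):
        res = run_experiment(two_locus_design(seed=1), ["GLEAM1"], n_replicates=0)
        assert res.per_replicate.empty

    def test_two_locus_summary_has_expected_accounting(self):
        res = run_experiment(two_locus_design(seed=2, n_replicates=2), ["GLEAM1"])
        tab = res.frequency_table()
        assert set(tab.columns) == {"REG1", "REG2", "REG3", "Locus1", "Locus2",
                                    "Locus12"}
        row = tab.loc["GLEAM1"]
        assert row[["Locus1", "Locus2", "Locus12"]].sum() <= 1.0 + 1e-12

    def test_null_summary_reports_rates(self):
        design = null_design(n_loci=60, n_subjects=150, n_trait_sets=2,
                             n_replicates=2, seed=3)
        res = run_experiment(design, ["GLEAM1"])
        tab = res.type1_summary()
        assert "median" in tab.columns
        assert (tab["median"] >= 0).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown methods"):
            run_experiment(two_locus_design(seed=4), ["BLR"], n_replicates=1)


def test_sim_design_validation():
    with pytest.raises(ValueError):
        SimDesign(causal_idx=(5,), c=(0.4,), n_loci=3)
    with pytest.raises(ValueError):
        SimDesign(causal_idx=(0,), c=(), n_loci=3)
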