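import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oracles import ols_slope_se
from pgskit import simdata, sumstats as ss


class TestSimulateGenotypes:
    def test_ld_decays_with_genetic_distance(self):
        panel = simdata.simulate_genotypes(2_000, 500, ld_decay=1.0, seed=1,
                                           spacing_cm=0.05,
                                           n_founder_haplotypes=20)
        G = panel.genotypes.astype(float)
        Z = (G - G.mean(0)) / G.std(0)
        n = G.shape[0]
        rng = np.random.default_rng(0)
        r2, dist = [], []
        for _ in range(3_000):
            j = rng.integers(0, 499)
            k = rng.integers(max(0, j - 40), min(500, j + 40))
            if j == k:
                continue
            r2.append(float(Z[:, j] @ Z[:, k] / n) ** 2)
            dist.append(abs(panel.pos_cm[j] - panel.pos_cm[k]))
        rho, pval = spearmanr(r2, dist)
        assert rho < 0 and pval < 0.01

    def test_infinite_decay_gives_independence(self):
        panel = simdata.simulate_genotypes(3_000, 100, ld_decay=np.inf,
                                           seed=2, n_founder_haplotypes=20)
        G = panel.genotypes.astype(float)
        r_adj = np.array([np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
                          for j in range(99)])
        # |r| at the 1/sqrt(n) sampling-noise level, same as distant pairs
        assert np.mean(np.abs(r_adj)) < 3.0 / np.sqrt(3_000)

    def test_two_founders_no_recombination_gives_perfect_ld(self):
        panel = simdata.simulate_genotypes(500, 60, ld_decay=0.0, seed=3,
                                           n_founder_haplotypes=2,
                                           maf_range=(0.2, 0.5))
        G = panel.genotypes.astype(float)
        informative = np.flatnonzero(panel.founders[0] != panel.founders[1])
        r2 = [np.corrcoef(G[:, j], G[:, k])[0, 1] ** 2
              for j, k in zip(informative[:-1], informative[1:])]
        assert np.min(r2) > 0.99

    def test_maf_within_range_and_invariants(self, small_panel):
        small_panel.validate()
        maf = np.minimum(small_panel.freq, 1 - small_panel.freq)
        assert maf.min() >= 0.01 and maf.max() <= 0.5

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(n_individuals=10, n_variants=0), "empty"),
        (dict(n_individuals=10, n_variants=5, maf_range=(0.0, 0.5)), "maf_range"),
        (dict(n_individuals=10, n_variants=5, maf_range=(0.6, 0.7)), "maf_range"),
    ])
    def test_argument_errors(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simdata.simulate_genotypes(**kwargs)

    def test_round_trip_serialization(self, small_panel, tmp_path):
        prefix = str(tmp_path / "panel")
        small_panel.save(prefix)
        back = simdata.GenotypePanel.load(prefix)
        assert np.array_equal(back.genotypes, small_panel.genotypes)
        assert np.array_equal(back.pos_cm, small_panel.pos_cm)


class TestSimulateDosages:
    def test_info_one_is_identity(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 1.0, seed=4)
        assert np.array_equal(dos.dosages, small_panel.genotypes.astype(float))

    def test_half_info_shrinks_sd_by_sqrt_half(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 0.5, seed=5)
        ratio = dos.dosages.std(0, ddof=1) / \
            small_panel.genotypes.astype(float).std(0, ddof=1)
        assert abs(np.median(ratio) - np.sqrt(0.5)) < 0.02

    def test_conditional_expectation_property(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 0.6, seed=6)
        G = small_panel.genotypes.astype(float)
        D = dos.dosages
        ratios = np.array([np.cov(D[:, j], G[:, j])[0, 1]
                           / D[:, j].var(ddof=1)
                           for j in range(small_panel.n_variants)])
        assert abs(ratios.mean() - 1.0) < 0.01
        assert np.all(np.abs(ratios - 1.0) < 0.15)

    def test_realized_info_tracks_target(self, small_panel):
        target = np.random.default_rng(7).uniform(0.3, 1.0,
                                                  small_panel.n_variants)
        dos = simdata.simulate_dosages(small_panel, target, seed=7)
        dev = dos.realized_info - target
        assert abs(dev.mean()) < 0.005
        assert np.abs(dev).max() < 0.08  # per-variant sampling noise at n=2,000

    def test_dosages_bounded(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 0.4, seed=8)
        assert dos.dosages.min() >= 0.0 and dos.dosages.max() <= 2.0

    def test_invalid_info_rejected(self, small_panel):
        with pytest.raises(ValueError, match="target_info"):
            simdata.simulate_dosages(small_panel, 0.0)


class TestSimulatePhenotype:
    def test_h2_zero_is_pure_noise(self, small_panel):
        pm = simdata.simulate_phenotype(small_panel, 0.0, 10, seed=9)
        assert np.all(pm.genetic == 0) and pm.h2_realized == 0.0

    def test_h2_one_is_pure_genetics(self, small_panel):
        pm = simdata.simulate_phenotype(small_panel, 1.0, 10, seed=10)
        assert np.array_equal(pm.y, pm.genetic)

    def test_h2_exact_in_sample(self, small_panel):
        pm = simdata.simulate_phenotype(small_panel, 0.2, 25, seed=11)
        assert pm.h2_realized == pytest.approx(0.2, abs=1e-10)
        assert len(pm.causal_idx) == 25

    def test_paper_design_scaled_down(self):
        # 4,000 variants / 200 causal / h2 = 0.2, reduced-scale instance
        panel = simdata.simulate_genotypes(1_000, 4_000, seed=12,
                                           genetic_map="hotspot",
                                           n_founder_haplotypes=8,
                                           ld_decay=1.5)
        pm = simdata.simulate_phenotype(panel, 0.2, 200, seed=13)
        assert pm.h2_realized == pytest.approx(0.2, abs=0.01)

    def test_rescaling_can_be_disabled(self, small_panel):
        pm = simdata.simulate_phenotype(small_panel, 0.2, 25, seed=11,
                                        rescale_noise=False)
        # only MC-close to the target (25 causal draws), not exact
        assert 0.05 < pm.h2_realized < 0.4
        assert pm.h2_realized != pytest.approx(0.2, abs=1e-10)

    def test_invalid_h2_rejected(self, small_panel):
        with pytest.raises(ValueError, match="h2"):
            simdata.simulate_phenotype(small_panel, 1.5, 10)


class TestRunGwasLinear:
    def test_perfect_fit_has_zero_se(self):
        rng = np.random.default_rng(14)
        G = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
        panel_y = G[:, 1].astype(float)
        stats = simdata.run_gwas_linear(G, panel_y, 1.0, seed=15)
        assert stats.df.loc[1, "beta"] == pytest.approx(1.0)
        assert stats.df.loc[1, "beta_se"] == pytest.approx(0.0, abs=1e-8)

    def test_five_individual_toy_matches_textbook_ols(self):
        g = np.array([[0], [1], [2], [1], [0]], dtype=np.int8)
        y = np.array([0.1, 1.2, 1.9, 0.8, 0.0])
        stats = simdata.run_gwas_linear(g, y, 1.0, seed=16)
        slope, se = ols_slope_se(g.ravel(), y)
        assert stats.df.loc[0, "beta"] == pytest.approx(slope)
        assert stats.df.loc[0, "beta_se"] == pytest.approx(se)

    def test_sd_identity_consistency(self, small_panel, small_pheno,
                                     small_gwas):
        """The sd identity: sd inferred from (beta, se, n) matches the
        empirical genotype sd, slope 1 +- 0.01."""
        sd_ss = ss.sd_from_sumstats(small_gwas,
                                    sd_y=small_pheno.y.std(ddof=1))
        emp = small_panel.genotypes.astype(float).std(0, ddof=1)
        slope = (sd_ss @ emp) / (emp @ emp)
        assert slope == pytest.approx(1.0, abs=0.01)
        assert np.abs(sd_ss / emp - 1).max() < 0.01

    def test_subsample_sizes_recorded(self, small_panel, small_pheno):
        frac = np.full(small_panel.n_variants, 0.5)
        stats = simdata.run_gwas_linear(small_panel, small_pheno.y, frac,
                                        seed=17)
        assert np.all(stats.df["n"] == round(0.5 * small_panel.n_individuals))

    def test_zero_variance_variant_flagged_missing(self):
        G = np.zeros((30, 2), dtype=np.int8)
        G[:, 1] = np.tile([0, 1, 2], 10)
        y = np.random.default_rng(18).standard_normal(30)
        stats = simdata.run_gwas_linear(G, y, 1.0, seed=19)
        assert np.isnan(stats.df.loc[0, "beta"])
        assert np.isfinite(stats.df.loc[1, "beta"])


@pytest.fixture(scope="module")
def mi_setup():
    panel = simdata.simulate_genotypes(1_500, 120, ld_decay=1.5, seed=20,
                                       n_founder_haplotypes=8,
                                       genetic_map="hotspot")
    pheno = simdata.simulate_phenotype(panel, 0.5, 20, seed=21)
    return panel, pheno


class TestMultipleImputation:
    def test_info_one_pooled_equals_single_gwas(self, mi_setup):
        panel, pheno = mi_setup
        dos = simdata.simulate_dosages(panel, 1.0, seed=22)
        mi = simdata.run_gwas_multiple_imputation(panel, dos, pheno.y,
                                                  n_imputations=3, seed=23)
        single = simdata.run_gwas_linear(panel, pheno.y, 1.0, seed=24)
        np.testing.assert_allclose(mi.df["beta"], single.df["beta"],
                                   atol=1e-10)

    def test_mi_effects_attenuated_by_info(self, mi_setup):
        panel, pheno = mi_setup
        info = 0.5
        dos = simdata.simulate_dosages(panel, info, seed=25)
        mi = simdata.run_gwas_multiple_imputation(panel, dos, pheno.y,
                                                  n_imputations=10, seed=26)
        imp = simdata.run_gwas_linear(dos, pheno.y, 1.0, seed=27)
        b_mi = mi.df["beta"].to_numpy()
        b_imp = imp.df["beta"].to_numpy()
        slope = (b_mi @ b_imp) / (b_imp @ b_imp)
        assert slope == pytest.approx(info, abs=0.1)

    def test_pooled_se_shrinks_with_more_imputations(self, mi_setup):
        panel, pheno = mi_setup
        dos = simdata.simulate_dosages(panel, 0.6, seed=28)
        se2 = simdata.run_gwas_multiple_imputation(
            panel, dos, pheno.y, n_imputations=2, seed=29).df["beta_se"]
        se20 = simdata.run_gwas_multiple_imputation(
            panel, dos, pheno.y, n_imputations=20, seed=29).df["beta_se"]
        assert se20.mean() < se2.mean()

    def test_too_few_imputations_rejected(self, mi_setup):
        panel, pheno = mi_setup
        dos = simdata.simulate_dosages(panel, 0.9, seed=30)
        with pytest.raises(ValueError, match="imputations"):
            simdata.run_gwas_multiple_imputation(panel, dos, pheno.y,
                                                 n_imputations=1)


class TestBuildScenario:
    def test_sample_size_fraction_counts_exact(self):
        sc = simdata.build_scenario("sample-size",
                                    {"n_individuals": 200, "n_variants": 8},
                                    seed=31)
        counts = pd.Series(sc.subsample_fractions).value_counts()
        assert counts[1.0] == 4 and counts[0.8] == 2 and counts[0.6] == 2
        expect = np.rint(sc.subsample_fractions * 200)
        assert np.array_equal(sc.gwas.df["n"].to_numpy(), expect)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simdata.build_scenario("nope")

    def test_seed_determinism(self):
        a = simdata.build_scenario("sample-size",
                                   {"n_individuals": 300, "n_variants": 50},
                                   seed=32)
        b = simdata.build_scenario("sample-size",
                                   {"n_individuals": 300, "n_variants": 50},
                                   seed=32)
        assert np.array_equal(a.panel.genotypes, b.panel.genotypes)
        pd.testing.assert_frame_equal(a.gwas.df, b.gwas.df)

    def test_zero_drift_shares_founder_pool(self):
        sc = simdata.build_scenario(
            "ld-mismatch",
            {"n_individuals": 300, "n_variants": 60, "drift": 0.0}, seed=33)
        assert np.array_equal(sc.panel.founders, sc.ld_panel.founders)
        assert np.array_equal(sc.panel.pos_cm, sc.ld_panel.pos_cm)

    def test_default_drift_keeps_frequencies_aligned(self):
        sc = simdata.build_scenario(
            "ld-mismatch", {"n_individuals": 1_000, "n_variants": 800},
            seed=34)
        r = np.corrcoef(sc.panel.freq, sc.ld_panel.freq)[0, 1]
        assert r > 0.97

    def test_dosage_scenario_info_one_makes_corrections_noops(self):
        # dosages equal genotypes at INFO=1; the recomputed INFO deviates
        # from 1 only by sampling noise, so every preset is a near-identity
        sc = simdata.build_scenario(
            "dosage",
            {"n_individuals": 2_000, "n_variants": 40,
             "info_range": (1.0, 1.0)}, seed=35)
        # the recomputed INFO can sit a few percent below 1 by sampling noise
        for name in ss.INFO_CORRECTIONS:
            corrected = ss.apply_info_correction(sc.gwas, name)
            np.testing.assert_allclose(corrected.df["beta"],
                                       sc.gwas.df["beta"], rtol=0.1,
                                       atol=1e-4)
            np.testing.assert_allclose(corrected.df["beta_se"],
                                       sc.gwas.df["beta_se"], rtol=0.1)
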