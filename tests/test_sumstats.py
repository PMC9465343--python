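import numpy as np
import pandas as pd
import pytest

from pgskit import simdata, sumstats as ss


def _stats(df, **kw):
    return ss.SumStats(pd.DataFrame(df), **kw)


class TestSdFromSumstats:
    def test_quantitative_plugin(self):
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.0], "beta_se": [0.01], "n": [10_000.0]},
                   n_total=10_000)
        assert ss.sd_from_sumstats(s, sd_y=1.0)[0] == pytest.approx(1.0)

    def test_binary_plugin(self):
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.0], "beta_se": [0.02], "n_eff": [10_000.0]},
                   trait_type="binary")
        assert ss.sd_from_sumstats(s)[0] == pytest.approx(1.0)

    def test_matches_empirical_sd_on_simulation(self, small_panel,
                                                small_pheno, small_gwas):
        sd_ss = ss.sd_from_sumstats(small_gwas,
                                    sd_y=small_pheno.y.std(ddof=1))
        emp = small_panel.genotypes.astype(float).std(0, ddof=1)
        assert np.abs(sd_ss / emp - 1).max() < 0.01


class TestSdFromAf:
    def test_hand_values(self):
        assert ss.sd_from_af(np.array([0.5]))[0] == pytest.approx(np.sqrt(0.5))
        assert ss.sd_from_af(np.array([0.5]),
                             np.array([0.64]))[0] == pytest.approx(0.565685,
                                                                   abs=1e-5)

    def test_out_of_range_freq_is_missing(self):
        out = ss.sd_from_af(np.array([0.0, 1.0, 0.3]))
        assert np.isnan(out[0]) and np.isnan(out[1]) and np.isfinite(out[2])

    def test_matches_dosage_sd(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 0.7, seed=40)
        sd_af = ss.sd_from_af(dos.freq, dos.realized_info)
        emp = dos.dosages.std(0, ddof=1)
        assert np.abs(sd_af / emp - 1).max() < 0.02


class TestEstimateVarY:
    def test_constant_vector(self):
        m = 150
        s = _stats({"chr": "1", "pos": np.arange(m), "a0": "A", "a1": "C",
                    "beta": np.zeros(m),
                    "beta_se": np.full(m, np.sqrt(2.0 / 1000)),
                    "n": np.full(m, 1000.0)}, n_total=1000)
        assert ss.estimate_var_y(s) == pytest.approx(1.0)

    def test_simulated_gwas_recovers_unit_variance(self, small_gwas,
                                                   small_pheno):
        vy = ss.estimate_var_y(small_gwas)
        assert vy == pytest.approx(np.var(small_pheno.y, ddof=1), rel=0.05)

    def test_percentile_robust_to_one_outlier(self):
        m = 10_000
        rng = np.random.default_rng(41)
        se = np.sqrt(2.0 / (1000 * 2 * rng.uniform(0.05, 0.5, m)
                            * (1 - rng.uniform(0.05, 0.5, m))))
        df = {"chr": "1", "pos": np.arange(m), "a0": "A", "a1": "C",
              "beta": np.zeros(m), "beta_se": se, "n": np.full(m, 1000.0)}
        base = ss.estimate_var_y(_stats(df, n_total=1000))
        df_out = dict(df)
        df_out["beta_se"] = se.copy()
        df_out["beta_se"][0] = 100.0
        perturbed = ss.estimate_var_y(_stats(df_out, n_total=1000))
        assert perturbed == pytest.approx(base, abs=1e-3)

    def test_binary_trait_directed_to_neff_path(self):
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.1], "beta_se": [0.01], "n_eff": [100.0]},
                   trait_type="binary")
        with pytest.raises(ValueError, match="effective-n"):
            ss.estimate_var_y(s)


class TestImputeN:
    def test_round_trip_inverts_sd_identity(self):
        rng = np.random.default_rng(42)
        m = 50
        f = rng.uniform(0.05, 0.95, m)
        var_g = 2 * f * (1 - f)
        n = rng.integers(5_000, 20_000, m).astype(float)
        beta = rng.normal(0, 0.05, m)
        var_y = 1.7
        se = np.sqrt((var_y / var_g - beta**2) / n)
        s = _stats({"chr": "1", "pos": np.arange(m), "a0": "A", "a1": "C",
                    "beta": beta, "beta_se": se, "freq": f},
                   n_total=float(n.max()), var_y=var_y)
        out = ss.impute_n(s, var_y=var_y, clamp=None)
        np.testing.assert_allclose(out["n_raw"], n, rtol=1e-10)

    def test_binary_hand_value(self):
        # var(G)=0.32, beta=0, se=0.0125 -> n_eff = (4/0.32)/0.0125^2 = 80,000
        f = 0.5 - np.sqrt(0.25 - 0.16)  # 2f(1-f) = 0.32
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.0], "beta_se": [0.0125], "freq": [f]},
                   trait_type="binary", n_total=80_000)
        out = ss.impute_n(s, clamp=None)
        assert out["n_raw"][0] == pytest.approx(80_000, rel=1e-10)

    def test_clamping_and_flag(self):
        # truth n = 0.3 N -> clamped up to 0.5 N with the flag set
        N = 10_000.0
        f, var_y = 0.3, 1.0
        var_g = 2 * f * (1 - f)
        se = np.sqrt(var_y / var_g / (0.3 * N))
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.0], "beta_se": [se], "freq": [f]},
                   n_total=N, var_y=var_y)
        out = ss.impute_n(s, var_y=var_y)
        assert out["n_imputed"][0] == pytest.approx(0.5 * N)
        assert bool(out["clamped"][0])
        assert out["n_raw"][0] == pytest.approx(0.3 * N, rel=1e-9)


class TestEffectiveSampleSize:
    def test_balanced_equals_total(self):
        assert ss.effective_sample_size(500, 500) == pytest.approx(1000)

    def test_hand_value(self):
        assert ss.effective_sample_size(500, 2000) == pytest.approx(1600)

    def test_zero_count_meta_analysis_is_zero(self):
        assert ss.effective_sample_size([1000, 0], [0, 1000]) == 0.0

    def test_meta_analysis_sums_per_study(self):
        v = ss.effective_sample_size([500, 500], [500, 2000])
        assert v == pytest.approx(1000 + 1600)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ss.effective_sample_size(-1, 10)


class TestScaledEffects:
    def test_hand_value(self):
        # beta = se, n = 3 -> scaled = 1/2
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.2], "beta_se": [0.2], "n": [3.0]},
                   n_total=3, var_y=1.0)
        assert ss.scaled_effects(s).beta_scaled[0] == pytest.approx(0.5)

    def test_equals_marginal_correlation(self, small_panel, small_pheno,
                                         small_gwas):
        scaled = ss.scaled_effects(small_gwas)
        G = small_panel.genotypes.astype(float)
        idx = np.arange(0, small_panel.n_variants, 23)
        emp = np.array([np.corrcoef(G[:, j], small_pheno.y)[0, 1]
                        for j in idx])
        np.testing.assert_allclose(scaled.beta_scaled[idx], emp, atol=0.01)

    def test_round_trip_is_identity(self, small_gwas):
        scaled = ss.scaled_effects(small_gwas)
        gamma = ss.per_allele_effects(scaled.beta_scaled, scaled)
        np.testing.assert_allclose(gamma, small_gwas.df["beta"], rtol=1e-12)

    def test_sign_and_magnitude_invariants(self, small_scaled, small_gwas):
        b = small_scaled.beta_scaled
        assert np.nanmax(np.abs(b)) < 1.0
        signs = np.sign(small_gwas.df["beta"].to_numpy())
        ok = signs != 0
        assert np.all(np.sign(b[ok]) == signs[ok])
        assert np.all(small_scaled.sd_ss[np.isfinite(small_scaled.sd_ss)] > 0)


class TestInfoCorrection:
    def test_presets_identity_at_full_info(self, toy_sumstats):
        df = toy_sumstats.df.copy()
        df["info"] = 1.0
        s = toy_sumstats.with_df(df)
        for name in ss.INFO_CORRECTIONS:
            out = ss.apply_info_correction(s, name)
            pd.testing.assert_frame_equal(out.df, s.df)

    def test_sqrt_info_preserves_z(self, toy_sumstats):
        out = ss.apply_info_correction(toy_sumstats, "sqrt_info")
        np.testing.assert_allclose(
            out.column("beta") / out.column("beta_se"),
            toy_sumstats.column("beta") / toy_sumstats.column("beta_se"))

    def test_info_preset_preserves_se_and_scales_n(self, toy_sumstats):
        out = ss.apply_info_correction(toy_sumstats, "info")
        np.testing.assert_allclose(out.column("beta_se"),
                                   toy_sumstats.column("beta_se"))
        np.testing.assert_allclose(
            out.column("n"),
            toy_sumstats.column("n") * toy_sumstats.column("info"))

    def test_sqrt_info_hand_value(self):
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.10], "beta_se": [0.020], "info": [0.64]})
        out = ss.apply_info_correction(s, "sqrt_info")
        assert out.df["beta"][0] == pytest.approx(0.08)
        assert out.df["beta_se"][0] == pytest.approx(0.016)

    def test_unknown_preset_rejected(self, toy_sumstats):
        with pytest.raises(ValueError, match="unknown correction"):
            ss.apply_info_correction(toy_sumstats, "info2")

    def test_provenance_recorded(self, toy_sumstats):
        out = ss.apply_info_correction(toy_sumstats, "in_between")
        assert out.meta["info_correction"] == "in_between"


class TestPowerRatio:
    def test_identical_vectors_give_one(self):
        x = np.array([5.0, 9.0, 30.0])
        mask = np.ones(3, dtype=bool)
        v, _ = ss.estimate_power_ratio(x, x, mask)
        assert v == pytest.approx(1.0)

    def test_uniform_boost(self):
        x = np.array([5.0, 9.0, 30.0])
        mask = np.ones(3, dtype=bool)
        for summary in ("mean_of_ratios", "ratio_of_means"):
            v, _ = ss.estimate_power_ratio(1.2 * x, x, mask, summary)
            assert v == pytest.approx(1.2)

    def test_summaries_differ_on_heteroskedastic_input(self):
        boosted = np.array([2.0, 10.0, 100.0])
        linear = np.array([1.0, 10.0, 50.0])
        mask = np.ones(3, dtype=bool)
        _, diag = ss.estimate_power_ratio(boosted, linear, mask)
        assert diag["mean_of_ratios"] != pytest.approx(diag["ratio_of_means"])
        assert diag["mean_of_ratios"] == pytest.approx((2 + 1 + 2) / 3)
        assert diag["ratio_of_means"] == pytest.approx(112 / 61)

    def test_invariances(self):
        rng = np.random.default_rng(43)
        b = rng.uniform(1, 5, 20)
        l = rng.uniform(1, 5, 20)
        mask = np.ones(20, dtype=bool)
        perm = rng.permutation(20)
        for summary in ("mean_of_ratios", "ratio_of_means"):
            v0, _ = ss.estimate_power_ratio(b, l, mask, summary)
            vp, _ = ss.estimate_power_ratio(b[perm], l[perm], mask, summary)
            vs, _ = ss.estimate_power_ratio(3 * b, 3 * l, mask, summary)
            assert vp == pytest.approx(v0)
            assert vs == pytest.approx(v0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no variants"):
            ss.estimate_power_ratio(np.ones(3), np.ones(3),
                                    np.zeros(3, dtype=bool))


class TestGlobalNeffPercentile:
    def test_constant_vector(self):
        assert ss.global_neff_percentile(np.full(10, 7.0), 80) == 7.0

    def test_linear_interpolation_convention(self):
        v = ss.global_neff_percentile(np.arange(1.0, 101.0), 80)
        assert v == pytest.approx(80.2)

    def test_tracks_upper_plateau_in_mixture(self):
        rng = np.random.default_rng(44)
        full = rng.normal(100_000, 2_000, 7_000)
        halved = rng.normal(50_000, 2_000, 3_000)
        neff = np.concatenate([full, halved])
        est, ratio = ss.global_neff_percentile(neff, 80,
                                               reported_neff=100_000)
        assert est == pytest.approx(100_000, rel=0.05)
        assert est > neff.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.global_neff_percentile(np.array([np.nan]))


class TestRecomputeInfo:
    def test_hard_hwe_genotypes_near_one(self, small_panel):
        info = ss.recompute_info(small_panel.genotypes.astype(float))
        assert np.nanmedian(info) > 0.95

    def test_round_trip_with_simulator(self, small_panel):
        dos = simdata.simulate_dosages(small_panel, 0.7, seed=45)
        info = ss.recompute_info(dos)
        assert abs(np.mean(info) - 0.7) < 0.02

    def test_constant_column_flagged_missing_not_zero(self):
        D = np.column_stack([np.full(100, 1.0),
                             np.tile([0.2, 1.8], 50)])
        info = ss.recompute_info(D)
        assert np.isnan(info[0]) and np.isfinite(info[1])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="2 individuals"):
            ss.recompute_info(np.ones((1, 3)))


class TestSumStatsContainer:
    def test_required_columns_enforced(self):
        with pytest.raises(ValueError, match="missing required"):
            ss.SumStats(pd.DataFrame({"chr": ["1"], "pos": [1]}))

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "A",
                    "beta": [0.1], "beta_se": [0.1]})

    def test_binary_neff_derived_from_counts(self):
        s = _stats({"chr": "1", "pos": [1], "a0": "A", "a1": "C",
                    "beta": [0.1], "beta_se": [0.1]},
                   trait_type="binary", n_cases=500, n_controls=2000)
        assert s.n[0] == pytest.approx(1600)

    def test_reader_translates_headers(self, tmp_path):
        p = tmp_path / "ss.tsv"
        pd.DataFrame({
            "CHR": ["1"], "BP": [100], "other_allele": ["A"],
            "effect_allele": ["C"], "Effect": [0.1], "SE": [0.01],
            "EAF": [0.3],
        }).to_csv(p, sep="\t", index=False)
        s = ss.read_sumstats(p, n_total=1000)
        for col in ("chr", "pos", "a0", "a1", "beta", "beta_se", "freq"):
            assert col in s.df.columns

    def test_reader_explicit_mapping_error_lists_headers(self, tmp_path):
        p = tmp_path / "ss.tsv"
        pd.DataFrame({"c": ["1"], "p": [1]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="available"):
            ss.read_sumstats(p, column_map={"chr": "chrom"})
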