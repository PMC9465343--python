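"""Estimate heritability and polygenicity with the auto sampler, and see
the robust variant contain the damage when per-variant sample sizes are
misspecified."""

import numpy as np

from pgskit import ldpred2, ldref, simdata, sumstats as ss

panel = simdata.simulate_genotypes(8_000, 1_500, ld_decay=1.5,
                                   n_founder_haplotypes=8, seed=21,
                                   genetic_map="hotspot")
pheno = simdata.simulate_phenotype(panel, h2=0.2, n_causal=75, seed=22)
ld = ldref.build_ld(panel, window_cm=3.0)
cfg = ldpred2.GibbsConfig(h2=0.1, n_chains=5, burn_in=100, num_iter=250,
                          seed=23)

# 1) well-specified: full-sample GWAS, every variant uses all individuals
gwas = simdata.run_gwas_linear(panel, pheno.y, seed=24)
scaled = ss.scaled_effects(gwas)
auto = ldpred2.gibbs_fit(np.nan_to_num(scaled.beta_scaled), ld, scaled.n,
                         cfg, mode="auto")
print("true h2 = 0.20, true p = 0.05")
print(f"well-specified GWAS:        h2 = {auto.h2_est:.3f}, "
      f"p = {auto.p_est:.3f}")

# 2) heterogeneous per-variant n (a meta-analysis), reported as one max n
frac = simdata.assign_subsample_fractions(
    1_500, (1.0, 0.8, 0.6), (0.5, 0.25, 0.25), np.random.default_rng(25))
gwas_mix = simdata.run_gwas_linear(panel, pheno.y, frac, seed=26)
n_max = np.full(1_500, float(gwas_mix.df["n"].max()))
wrong = ss.SumStats(gwas_mix.df.assign(n=n_max),
                    n_total=gwas_mix.n_total, var_y=gwas_mix.var_y)
scaled_w = ss.scaled_effects(wrong)
bh_w = np.nan_to_num(scaled_w.beta_scaled)
plain = ldpred2.gibbs_fit(bh_w, ld, n_max, cfg, mode="auto")
rob_cfg = ldpred2.GibbsConfig(h2=0.1, n_chains=5, burn_in=100, num_iter=250,
                              seed=23, **ldpred2.AUTO_ROB_SIMULATION)
rob = ldpred2.gibbs_fit(bh_w, ld, n_max, rob_cfg, mode="auto")
print(f"misspecified n, plain auto: p = {plain.p_est:.3f} "
      "(drifts toward 1 -> behaves as an infinitesimal model)")
print(f"misspecified n, auto-rob:   p = {rob.p_est:.3f} "
      "(shrink_corr=0.9 + no sign jumps keep p in range)")
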