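"""Scaled-down benchmark harness for the three misspecification experiments.

Runs, per seed: simulate a panel -> split disjoint train/validation/test
individuals -> GWAS on the training set -> fit each requested method (tuning
on validation where applicable) -> score squared correlation between the PGS
and the phenotype on held-out test individuals.  Aggregates per-seed results
with non-parametric bootstrap confidence intervals of the mean.

Desk scale (see docs/methods.md): 4,000 variants, 20,000/2,000/5,000
train/validation/test individuals, 10 seeds, so a full experiment runs in a
few minutes on one core rather than reproducing biobank-scale absolute
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import ldpred2, simdata, sumstats as ss
from .lassosum2 import LassosumGrid, fit_lassosum2, pick_best
from .ldref import apply_blocks, build_ld, ld_scores, split_blocks

__all__ = ["BenchConfig", "bootstrap_ci", "run_benchmark", "run_seed"]

METHODS = ("lassosum2", "ldpred2-inf", "ldpred2-grid", "ldpred2-low-h2",
           "ldpred2-auto", "ldpred2-auto-rob")


@dataclass
class BenchConfig:
    n_variants: int = 4_000
    n_train: int = 20_000
    n_val: int = 2_000
    n_test: int = 5_000
    h2: float = 0.2
    n_causal_frac: float = 0.05
    maf_range: tuple = (0.01, 0.5)
    ld_decay: float = 1.5
    n_founders: int = 8
    genetic_map: str = "hotspot"
    spacing_cm: float = 0.05
    window_cm: float = 3.0
    # hyper-parameter search, trimmed to desk scale
    p_grid: tuple = (0.003, 0.01, 0.03, 0.1, 0.3)
    grid_burn_in: int = 50
    grid_num_iter: int = 100
    auto_chains: int = 5
    auto_burn_in: int = 100
    auto_num_iter: int = 250
    # scenario knobs
    fractions: tuple = (1.0, 0.8, 0.6)
    proportions: tuple = (0.5, 0.25, 0.25)
    info_range: tuple = (0.3, 1.0)
    drift: float = 0.02
    # blocks: around twelve per chromosome-22-sized panel.  With the count
    # already pinned, boundary placement should minimize discarded
    # correlation, so the size-balance weight is kept tiny at this scale.
    max_block_size: int = 500
    max_r2: float = 0.3
    n_blocks_range: tuple = (10, 14)
    split_weight: float = 1e-4
    n_bootstrap: int = 1_000

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_val + self.n_test

    @property
    def n_causal(self) -> int:
        return max(1, int(round(self.n_causal_frac * self.n_variants)))


def bootstrap_ci(values, n_boot: int = 1_000, seed: int = 0,
                 level: float = 0.95):
    """Non-parametric bootstrap CI of the mean of per-seed values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(v.mean()), (float(np.quantile(means, alpha)),
                             float(np.quantile(means, 1.0 - alpha)))


def _r2(score: np.ndarray, y: np.ndarray) -> float:
    if np.std(score) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(score, y)[0, 1] ** 2)


def _score_columns(X, W, y):
    """r^2 of X @ W[:, k] with y, for every column k."""
    S = X @ W
    S = S - S.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((S**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (S.T @ yc) / denom, 0.0)
    return r**2


def _sub_panel(panel: simdata.GenotypePanel, rows) -> simdata.GenotypePanel:
    G = panel.genotypes[rows]
    return simdata.GenotypePanel(genotypes=G, freq=G.mean(axis=0) / 2.0,
                                 pos_bp=panel.pos_bp, pos_cm=panel.pos_cm,
                                 chrom=panel.chrom)


@dataclass
class _SeedData:
    panel: simdata.GenotypePanel
    pheno: simdata.PhenoModel
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    gwas: "ss.SumStats"
    fractions: np.ndarray | None
    ld: "object"
    ld_alt: "object" = None
    dosage_gwas: "ss.SumStats" = None


def _make_seed_data(scenario: str, cfg: BenchConfig, seed: int) -> _SeedData:
    rng = np.random.default_rng(seed)
    s_panel, s_pheno, s_gwas, s_extra = (int(x) for x in
                                         rng.integers(0, 2**31 - 1, size=4))
    panel = simdata.simulate_genotypes(
        cfg.n_total, cfg.n_variants, maf_range=cfg.maf_range,
        ld_decay=cfg.ld_decay, n_founder_haplotypes=cfg.n_founders,
        seed=s_panel, spacing_cm=cfg.spacing_cm,
        genetic_map=cfg.genetic_map)
    pheno = simdata.simulate_phenotype(panel, cfg.h2, cfg.n_causal,
                                       seed=s_pheno)
    idx = np.arange(cfg.n_total)
    train = idx[:cfg.n_train]
    val = idx[cfg.n_train:cfg.n_train + cfg.n_val]
    test = idx[cfg.n_train + cfg.n_val:]
    train_panel = _sub_panel(panel, train)
    y_train = pheno.y[train]

    fractions = None
    dosage_gwas = None
    ld_alt = None
    if scenario == "sample-size":
        fractions = simdata.assign_subsample_fractions(
            cfg.n_variants, cfg.fractions, cfg.proportions,
            np.random.default_rng(s_extra))
        gwas = simdata.run_gwas_linear(train_panel, y_train, fractions,
                                       seed=s_gwas)
    elif scenario == "dosage":
        info = np.random.default_rng(s_extra).uniform(*cfg.info_range,
                                                      size=cfg.n_variants)
        dos = simdata.simulate_dosages(train_panel, info, seed=s_extra,
                                       dtype=np.float32)
        dosage_gwas = simdata.run_gwas_linear(dos, y_train, 1.0, seed=s_gwas)
        gwas = dosage_gwas
    elif scenario == "ld-mismatch":
        gwas = simdata.run_gwas_linear(train_panel, y_train, 1.0, seed=s_gwas)
        rng2 = np.random.default_rng(s_extra)
        alt_founders = simdata.drift_founders(panel.founders, panel.freq,
                                              cfg.drift, rng2)
        alt_panel = simdata.simulate_genotypes(
            cfg.n_val, cfg.n_variants, maf_range=cfg.maf_range,
            ld_decay=cfg.ld_decay, seed=int(rng2.integers(0, 2**31 - 1)),
            genetic_map=panel.pos_cm, _founder_pool=alt_founders)
        ld_alt = build_ld(alt_panel, window_cm=cfg.window_cm)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    ld = build_ld(_sub_panel(panel, val), window_cm=cfg.window_cm)
    return _SeedData(panel=panel, pheno=pheno, train=train, val=val,
                     test=test, gwas=gwas, fractions=fractions, ld=ld,
                     ld_alt=ld_alt, dosage_gwas=dosage_gwas)


def _with_n(stats: "ss.SumStats", n_treatment: str,
            cfg: BenchConfig) -> "ss.SumStats":
    """Sample-size treatment: true per-variant n, the max as a single value,
    or n imputed from the statistics themselves."""
    if n_treatment == "true":
        return stats
    df = stats.df.copy()
    if n_treatment == "max":
        df["n"] = float(np.nanmax(stats.n))
    elif n_treatment == "imputed":
        imp = ss.impute_n(stats)
        df["n"] = imp["n_imputed"].to_numpy()
    else:
        raise ValueError(f"unknown sample-size treatment {n_treatment!r}")
    return stats.with_df(df, n_treatment=n_treatment)


def _fit_methods(stats, ld, data: _SeedData, cfg: BenchConfig,
                 methods, seed: int) -> dict:
    """Fit each method on one (stats, LD) pair; returns method -> test r2.

    ldpred2-grid and ldpred2-low-h2 share one sweep over the 6-multiplier h2
    grid; the plain grid selects only among the {0.3, 0.7, 1, 1.4}
    multipliers.
    """
    scaled = ss.scaled_effects(stats)
    beta_hat = np.nan_to_num(scaled.beta_scaled)
    inv_sd = np.nan_to_num(1.0 / scaled.sd_ss, nan=0.0, posinf=0.0)
    n_vec = scaled.n
    X_val = data.panel.genotypes[data.val].astype(np.float64)
    X_test = data.panel.genotypes[data.test].astype(np.float64)
    y_val = data.pheno.y[data.val]
    y_test = data.pheno.y[data.test]
    out = {}

    need_ldsc = any(m.startswith("ldpred2") and m != "ldpred2-auto"
                    for m in methods)
    h2_ldsc = None
    if need_ldsc:
        lsc = ld_scores(ld)
        fit = ldpred2.ldsc_h2(np.nan_to_num(scaled.z), lsc, n_vec,
                              M=len(beta_hat))
        h2_ldsc = float(np.clip(fit.h2, 1e-3, 1.0))

    if "lassosum2" in methods:
        path = fit_lassosum2(beta_hat, ld, n_vec, LassosumGrid())
        K = len(path.lambdas) * len(path.deltas)
        W = (path.betas.reshape(K, -1).T * inv_sd[:, None])
        val_r2 = _score_columns(X_val, W, y_val).reshape(len(path.lambdas),
                                                         len(path.deltas))
        val_r2[path.diverged] = np.nan
        _, _, beta = pick_best(path, val_r2)
        out["lassosum2"] = _r2(X_test @ (beta * inv_sd), y_test)

    if "ldpred2-inf" in methods:
        beta = ldpred2.fit_inf(beta_hat, ld, n_vec, h2_ldsc)
        out["ldpred2-inf"] = _r2(X_test @ (beta * inv_sd), y_test)

    if "ldpred2-grid" in methods or "ldpred2-low-h2" in methods:
        mult = np.asarray(ldpred2.H2_MULTIPLIERS["simulation"])
        h2_grid = mult * h2_ldsc
        gcfg = ldpred2.GibbsConfig(burn_in=cfg.grid_burn_in,
                                   num_iter=cfg.grid_num_iter, seed=seed)
        betas, mults = [], []
        for mu, h2 in zip(mult, h2_grid):
            for p in cfg.p_grid:
                res = ldpred2.gibbs_fit(
                    beta_hat, ld, n_vec,
                    replace(gcfg, p=float(p), h2=float(h2)), mode="grid")
                betas.append(res.beta)
                mults.append(mu)
        W = np.asarray(betas).T * inv_sd[:, None]
        val_r2 = _score_columns(X_val, W, y_val)
        standard = np.asarray(mults) >= 0.3  # the non-extended h2 grid
        if "ldpred2-grid" in methods:
            k = int(np.nanargmax(np.where(standard, val_r2, -np.inf)))
            out["ldpred2-grid"] = _r2(X_test @ W[:, k], y_test)
        if "ldpred2-low-h2" in methods:
            k = int(np.nanargmax(val_r2))
            out["ldpred2-low-h2"] = _r2(X_test @ W[:, k], y_test)

    for name, preset in (("ldpred2-auto", {}),
                         ("ldpred2-auto-rob", ldpred2.AUTO_ROB_SIMULATION)):
        if name not in methods:
            continue
        acfg = ldpred2.GibbsConfig(
            h2=h2_ldsc if h2_ldsc is not None else 0.1,
            burn_in=cfg.auto_burn_in, num_iter=cfg.auto_num_iter,
            n_chains=cfg.auto_chains, seed=seed, **preset)
        res = ldpred2.gibbs_fit(beta_hat, ld, n_vec, acfg, mode="auto")
        if res.all_diverged:
            out[name] = np.nan
        else:
            out[name] = _r2(X_test @ (res.beta * inv_sd), y_test)
    return out


def run_seed(scenario: str, cfg: BenchConfig, seed: int,
             methods=METHODS) -> pd.DataFrame:
    """All method/treatment combinations of one scenario for one seed.

    ``methods`` is either one method list for every treatment, or a dict
    mapping treatment name (including "blocks") to a method list.
    """
    data = _make_seed_data(scenario, cfg, seed)
    rows = []

    def add(method, n_treatment, ld_treatment, r2):
        rows.append({"scenario": scenario, "seed": seed, "method": method,
                     "n_treatment": n_treatment, "ld_treatment": ld_treatment,
                     "r2": r2})

    def methods_for(treatment):
        if isinstance(methods, dict):
            return methods.get(treatment, ())
        return methods

    if scenario == "sample-size":
        for treatment in ("true", "max", "imputed"):
            ms = methods_for(treatment)
            if not ms:
                continue
            stats = _with_n(data.gwas, treatment, cfg)
            res = _fit_methods(stats, data.ld, data, cfg, ms, seed)
            for mname, r2 in res.items():
                add(mname, treatment, "full", r2)
        # independent LD blocks, on the max-n (misspecified) statistics
        ms = methods_for("blocks")
        if ms:
            lo, hi = cfg.n_blocks_range
            split = split_blocks(data.ld, cfg.max_block_size,
                                 n_blocks_range=range(lo, hi + 1),
                                 max_r2=cfg.max_r2, weight=cfg.split_weight)
            if not split.feasible:  # drop the max_r2 guard, keep the count
                split = split_blocks(data.ld, cfg.max_block_size,
                                     n_blocks_range=range(lo, hi + 1),
                                     max_r2=1.0, weight=cfg.split_weight)
            ld_b = apply_blocks(data.ld, split)
            stats = _with_n(data.gwas, "max", cfg)
            res = _fit_methods(stats, ld_b, data, cfg, ms, seed)
            for mname, r2 in res.items():
                add(mname, "max", "blocks", r2)
    elif scenario == "dosage":
        for correction in ("none", "sqrt_info"):
            ms = methods_for(correction)
            if not ms:
                continue
            stats = data.dosage_gwas
            if correction != "none":
                stats = ss.apply_info_correction(stats, correction)
            res = _fit_methods(stats, data.ld, data, cfg, ms, seed)
            for mname, r2 in res.items():
                add(mname, correction, "full", r2)
    elif scenario == "ld-mismatch":
        for ld_treatment, ld in (("matched", data.ld),
                                 ("mismatched", data.ld_alt)):
            ms = methods_for(ld_treatment)
            if not ms:
                continue
            res = _fit_methods(data.gwas, ld, data, cfg, ms, seed)
            for mname, r2 in res.items():
                add(mname, "true", ld_treatment, r2)
    return pd.DataFrame(rows)


def run_benchmark(scenario: str, methods=METHODS, n_seeds: int = 10,
                  cfg: BenchConfig | None = None, seed: int = 0):
    """Run a scenario over seeds; returns (per-seed table, summary table).

    The summary aggregates per (method, n_treatment, ld_treatment) with the
    bootstrap CI of the mean test r^2; diverged fits appear as missing cells.
    """
    cfg = cfg or BenchConfig()
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_seeds)]
    tables = [run_seed(scenario, cfg, s, methods) for s in seeds]
    table = pd.concat(tables, ignore_index=True)
    rows = []
    for (m, nt, lt), grp in table.groupby(["method", "n_treatment",
                                           "ld_treatment"]):
        mean, (lo, hi) = bootstrap_ci(grp["r2"], cfg.n_bootstrap, seed=seed)
        rows.append({"method": m, "n_treatment": nt, "ld_treatment": lt,
                     "mean_r2": mean, "ci_low": lo, "ci_high": hi,
                     "n_seeds": int(grp["r2"].notna().sum())})
    return table, pd.DataFrame(rows)
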