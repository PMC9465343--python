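"""Synthetic genotype panels, imputed dosages, phenotypes and GWAS.

The generator is a mosaic-of-founder-haplotypes model: each haplotype copies
segments from a small pool of founder haplotypes, with recombination
breakpoints occurring at a configurable rate per cM.  This produces exact
{0,1,2} genotypes whose linkage disequilibrium decays with genetic distance
and vanishes beyond a few cM, which is what a windowed sparse LD matrix
assumes.  Imputed dosages are posterior-mean genotypes through a calibrated
Gaussian channel, so their variance ratio to the true genotypes equals the
target INFO score in expectation and cov(D, G) = var(D) holds exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sumstats as ss
from ._kernels import (gwas_per_variant, mosaic_haplotypes,
                       posterior_mean_dosage)

__all__ = [
    "GenotypePanel",
    "DosagePanel",
    "PhenoModel",
    "SimScenario",
    "simulate_genotypes",
    "simulate_dosages",
    "simulate_phenotype",
    "run_gwas_linear",
    "run_gwas_multiple_imputation",
    "build_scenario",
]


@dataclass
class GenotypePanel:
    """Hard genotypes (individuals x variants, values in {0,1,2}) plus maps."""

    genotypes: np.ndarray
    freq: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    chrom: str = "22"
    founders: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        if g.min() < 0 or g.max() > 2:
            raise ValueError("genotypes must lie in [0, 2]")
        if np.any(np.diff(self.pos_cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")
        if not np.allclose(g.mean(axis=0) / 2.0, self.freq, atol=1e-8):
            raise ValueError("freq must equal column means / 2")

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chr": self.chrom,
                "pos": self.pos_bp,
                "cm": self.pos_cm,
                "a0": "A",
                "a1": "C",
                "freq": self.freq,
            }
        )

    def save(self, prefix: str) -> None:
        """Binary container (.npz) plus a variant-metadata TSV."""
        np.savez(
            prefix + ".npz",
            genotypes=self.genotypes,
            freq=self.freq,
            pos_bp=self.pos_bp,
            pos_cm=self.pos_cm,
            chrom=np.array(self.chrom),
        )
        self.variant_table().to_csv(prefix + ".variants.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str) -> "GenotypePanel":
        z = np.load(prefix + ".npz")
        return cls(
            genotypes=z["genotypes"],
            freq=z["freq"],
            pos_bp=z["pos_bp"],
            pos_cm=z["pos_cm"],
            chrom=str(z["chrom"]),
        )


@dataclass
class DosagePanel:
    """Imputed allele dosages (continuous in [0, 2]) with INFO bookkeeping."""

    dosages: np.ndarray
    target_info: np.ndarray
    realized_info: np.ndarray
    freq: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    chrom: str = "22"
    # parameters of the construction, needed to form hard-call probabilities
    panel_freq: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    signal: np.ndarray | None = None  # G + eps, the noisy channel output

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PhenoModel:
    """A quantitative phenotype with known causal architecture."""

    causal_idx: np.ndarray
    effects_scaled: np.ndarray  # per causal variant, on the scaled-genotype scale
    h2_target: float
    n_causal: int
    y: np.ndarray
    genetic: np.ndarray
    trait_type: str = "quantitative"

    @property
    def h2_realized(self) -> float:
        vy = self.y.var()
        return float(self.genetic.var() / vy) if vy > 0 else 0.0


@dataclass
class SimScenario:
    """A generated truth set: panels, phenotype, GWAS output, bookkeeping."""

    name: str
    panel: GenotypePanel
    pheno: PhenoModel
    gwas: "ss.SumStats"
    seed: int
    subsample_fractions: np.ndarray | None = None
    dosages: DosagePanel | None = None
    ld_panel: GenotypePanel | None = None
    params: dict = field(default_factory=dict)


def hotspot_map(n_variants: int, rng, cold_cm: float = 0.01,
                hotspot_prob: float = 0.03,
                hotspot_mean_cm: float = 1.5) -> np.ndarray:
    """A genetic map with recombination hotspots: most inter-variant
    intervals are short (``cold_cm``), an occasional interval adds an
    exponential hotspot jump.  This is what makes real LD blocky and gives
    independent-block boundaries natural, cheap places to sit."""
    inc = np.full(n_variants, cold_cm)
    hot = rng.random(n_variants) < hotspot_prob
    inc[hot] += rng.exponential(hotspot_mean_cm, int(hot.sum()))
    inc[0] = 0.0
    return np.cumsum(inc)


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    ld_decay: float = 1.0,
    n_founder_haplotypes: int = 50,
    seed: int = 0,
    spacing_cm: float = 0.1,
    genetic_map="uniform",
    chrom: str = "22",
    _founder_pool: np.ndarray | None = None,
) -> GenotypePanel:
    """Generate a genotype panel with distance-decaying LD.

    ``ld_decay`` is the recombination rate per cM: adjacent-variant
    correlation decays as exp(-ld_decay * d_cM) times the founder-pool
    correlation.  ``ld_decay=inf`` gives independent variants.  Columns whose
    empirical MAF falls outside ``maf_range`` (including monomorphic ones) are
    resampled by redrawing their founder alleles.

    ``genetic_map`` is "uniform" (evenly spaced at ``spacing_cm``),
    "hotspot" (see :func:`hotspot_map`), or an explicit cM position array.
    ``_founder_pool`` lets scenario builders reuse (a drifted copy of) an
    existing founder pool so that two panels share their LD structure.
    """
    if n_variants <= 0:
        raise ValueError("empty panel: n_variants must be positive")
    if n_individuals <= 0:
        raise ValueError("empty panel: n_individuals must be positive")
    if n_founder_haplotypes < 2 and _founder_pool is None:
        raise ValueError("need at least 2 founder haplotypes")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    if ld_decay < 0:
        raise ValueError("ld_decay must be non-negative")

    rng = np.random.default_rng(seed)
    m = n_variants
    if isinstance(genetic_map, str):
        if genetic_map == "uniform":
            pos_cm = np.arange(m, dtype=np.float64) * spacing_cm
        elif genetic_map == "hotspot":
            pos_cm = hotspot_map(m, rng)
        else:
            raise ValueError(f"unknown genetic map {genetic_map!r}")
    else:
        pos_cm = np.asarray(genetic_map, dtype=np.float64)
        if pos_cm.shape != (m,) or np.any(np.diff(pos_cm) < 0):
            raise ValueError("genetic_map positions must be non-decreasing, "
                             "one per variant")
    pos_bp = (pos_cm * 1e6).astype(np.int64) + 1  # 1 cM = 1 Mbp fallback map

    if _founder_pool is not None:
        founders = np.ascontiguousarray(_founder_pool.astype(np.int8))
    else:
        if n_founder_haplotypes > 127:
            raise ValueError("founder pool limited to 127 haplotypes")
        p = rng.uniform(lo, hi, size=m)
        founders = (rng.random((n_founder_haplotypes, m)) < p).astype(np.int8)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    G, idx = mosaic_haplotypes(n_individuals, pos_cm, founders,
                               np.float64(ld_decay), kernel_seed)

    # resample columns whose empirical MAF escapes the requested range
    for _ in range(200):
        f = G.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        bad = np.flatnonzero((maf < lo) | (maf > hi))
        if bad.size == 0:
            break
        p_new = rng.uniform(max(lo, 0.1 * (lo + hi)), hi, size=bad.size)
        founders[:, bad] = (rng.random((founders.shape[0], bad.size)) < p_new).astype(np.int8)
        hap_bad = founders[idx[:, bad], bad[None, :]]
        G[:, bad] = hap_bad[0::2].astype(np.int8) + hap_bad[1::2].astype(np.int8)

    freq = G.mean(axis=0) / 2.0
    return GenotypePanel(genotypes=G, freq=freq, pos_bp=pos_bp, pos_cm=pos_cm,
                         chrom=chrom, founders=founders)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(40)


def _posterior_mean_var(f: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """E-xpected variance of D = E[G | G + eps] under HWE(f), eps ~ N(0,
    sigma^2), by Gauss-Hermite quadrature over the mixture channel output.
    Vectorized over variants."""
    f = np.atleast_1d(f)
    sigma = np.atleast_1d(sigma)
    g = np.array([0.0, 1.0, 2.0])
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)  # (m, 3)
    # s-nodes per component: s = g + sigma * x  -> (m, 3, q)
    s = g[None, :, None] + sigma[:, None, None] * _GH_NODES[None, None, :]
    # D(s) = sum_g' g' prior_g' N(s; g', sigma) / Z
    diff = s[:, :, :, None] - g[None, None, None, :]
    like = np.exp(-0.5 * (diff / sigma[:, None, None, None]) ** 2)
    w = prior[:, None, None, :] * like
    D = (w @ g) / w.sum(axis=-1)
    e_d2 = np.einsum("mcq,q,mc->m", D**2, _GH_WEIGHTS, prior) / _GH_WEIGHTS.sum()
    mean = 2.0 * f
    return e_d2 - mean**2


def _calibrate_sigma(f: np.ndarray, info: np.ndarray) -> np.ndarray:
    """Bisection for the channel noise sd giving var(D) = INFO * 2f(1-f)."""
    target = info * 2.0 * f * (1.0 - f)
    lo = np.full_like(f, 1e-3)
    hi = np.full_like(f, 50.0)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v = _posterior_mean_var(f, mid)
        too_big = v > target  # var(D) decreases in sigma
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    return 0.5 * (lo + hi)


def posterior_dosage(signal: np.ndarray, f: float, sigma: float) -> np.ndarray:
    """D = E[G | s] under HWE(f) and Gaussian channel noise."""
    g = np.array([0.0, 1.0, 2.0])
    prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    like = np.exp(-0.5 * ((signal[:, None] - g[None, :]) / sigma) ** 2)
    w = prior[None, :] * like
    return (w @ g) / w.sum(axis=1)


def simulate_dosages(
    panel: GenotypePanel,
    target_info,
    seed: int = 0,
    dtype=np.float64,
) -> DosagePanel:
    """Imputed dosages with a target INFO score per variant.

    The dosage is the posterior mean of the genotype through a Gaussian
    channel: D_j = E[G_j | G_j + eps_j] under the HWE prior at the panel
    frequency, with the channel noise sd calibrated per variant (by
    quadrature + bisection) so that var(D_j) = INFO_j * 2 f_j (1 - f_j).
    Being a true conditional expectation, D is bounded in [0, 2] (clipping is
    a no-op) and satisfies cov(D_j, G_j) = var(D_j) exactly in expectation.
    INFO = 1 yields D = G exactly.  The realized INFO is recomputed from the
    generated dosages and stored.
    """
    info = np.broadcast_to(np.asarray(target_info, dtype=np.float64),
                           (panel.n_variants,)).copy()
    if np.any(info <= 0) or np.any(info > 1):
        raise ValueError("target_info must lie in (0, 1] per variant")
    rng = np.random.default_rng(seed)
    G = panel.genotypes
    f = panel.freq
    exact = info >= 1.0 - 1e-12
    sigma = np.zeros_like(info)
    if (~exact).any():
        sigma[~exact] = _calibrate_sigma(f[~exact], info[~exact])
    n, m = G.shape
    D = np.empty((n, m), dtype=dtype)
    S = np.empty((n, m), dtype=dtype)
    chunk = max(1, int(4e7 / max(n, 1)))
    for j0 in range(0, m, chunk):
        j1 = min(m, j0 + chunk)
        sl = slice(j0, j1)
        S[:, sl] = G[:, sl].astype(dtype) \
            + rng.standard_normal((n, j1 - j0)).astype(dtype) \
            * sigma[sl].astype(dtype)
    posterior_mean_dosage(S, G, sigma, f, exact, D)
    np.clip(D, 0.0, 2.0, out=D)  # no-op safeguard; D is a posterior mean
    f_hat = D.mean(axis=0) / 2.0
    denom = 2.0 * f_hat * (1.0 - f_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        realized = np.where(denom > 0, D.var(axis=0, ddof=1) / denom, np.nan)
    realized = np.clip(realized, None, 1.0)
    return DosagePanel(
        dosages=D,
        target_info=info,
        realized_info=realized,
        freq=f_hat,
        pos_bp=panel.pos_bp,
        pos_cm=panel.pos_cm,
        chrom=panel.chrom,
        panel_freq=f.copy(),
        noise_sd=sigma,
        signal=S,
    )


def simulate_phenotype(
    panel: GenotypePanel,
    h2: float,
    n_causal: int,
    seed: int = 0,
    rescale_noise: bool = True,
) -> PhenoModel:
    """Quantitative phenotype with exact in-sample heritability.

    Causal variants are drawn uniformly without replacement; their effects on
    the scaled-genotype scale are i.i.d. N(0, h2 / n_causal).  The noise is
    orthogonalized against the genetic component and rescaled so that
    var(genetic) / var(y) equals h2 exactly in-sample (disable with
    ``rescale_noise=False`` to get plain N(0, 1-h2) noise).
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if not (1 <= n_causal <= panel.n_variants):
        raise ValueError("n_causal must lie in [1, n_variants]")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(panel.n_variants, size=n_causal, replace=False))
    effects = rng.normal(0.0, np.sqrt(h2 / n_causal) if h2 > 0 else 0.0,
                         size=n_causal)
    Gc = panel.genotypes[:, causal].astype(np.float64)
    sd = Gc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Gc - Gc.mean(axis=0)) / sd
    g = Z @ effects
    noise = rng.standard_normal(panel.n_individuals)
    if h2 >= 1.0:
        y = g
    elif h2 <= 0.0:
        g = np.zeros_like(noise)
        effects = np.zeros_like(effects)
        y = noise
    else:
        if rescale_noise:
            vg = g.var()
            noise = noise - noise.mean()
            if vg > 0:
                noise = noise - g * (noise @ (g - g.mean())) / (g.var() * len(g))
            target_ve = vg * (1.0 - h2) / h2
            sn = noise.std()
            noise = noise * (np.sqrt(target_ve) / sn if sn > 0 else 0.0)
        else:
            noise = noise * np.sqrt(1.0 - h2)
        y = g + noise
    return PhenoModel(
        causal_idx=causal,
        effects_scaled=effects,
        h2_target=float(h2),
        n_causal=int(n_causal),
        y=y,
        genetic=g,
    )


def _variant_frame(freq, used_n, pos_bp, pos_cm, chrom, beta, se, info=None):
    df = pd.DataFrame(
        {
            "chr": chrom,
            "pos": pos_bp,
            "a0": "A",
            "a1": "C",
            "beta": beta,
            "beta_se": se,
            "freq": freq,
            "n": used_n,
        }
    )
    if info is not None:
        df["info"] = info
    return df


def run_gwas_linear(
    panel,
    y: np.ndarray,
    subsample_fraction=1.0,
    seed: int = 0,
) -> "ss.SumStats":
    """Per-variant simple linear regression GWAS.

    ``panel`` may be a GenotypePanel, a DosagePanel, or a raw matrix.  Each
    variant is regressed on an independent seeded subsample of the stated
    fraction of individuals (mimicking a meta-analysis where cohorts cover
    different variants).  Zero-variance variants within their subsample get
    missing effect/se and are flagged.
    """
    info = None
    if isinstance(panel, GenotypePanel):
        X = panel.genotypes
        pos_bp, pos_cm, chrom = panel.pos_bp, panel.pos_cm, panel.chrom
    elif isinstance(panel, DosagePanel):
        X = panel.dosages
        pos_bp, pos_cm, chrom = panel.pos_bp, panel.pos_cm, panel.chrom
        info = panel.realized_info
    else:
        X = np.asarray(panel)
        pos_bp = np.arange(1, X.shape[1] + 1, dtype=np.int64)
        pos_cm = pos_bp.astype(np.float64) * 1e-6
        chrom = "22"
    n, m = X.shape
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != n:
        raise ValueError("phenotype length must equal the number of individuals")
    frac = np.broadcast_to(np.asarray(subsample_fraction, dtype=np.float64),
                           (m,)).copy()
    if np.any(frac <= 0) or np.any(frac > 1):
        raise ValueError("subsample fractions must lie in (0, 1]")
    counts = np.rint(frac * n).astype(np.int64)
    counts = np.clip(counts, 1, n)
    if not X.flags["C_CONTIGUOUS"]:
        X = np.ascontiguousarray(X)
    beta, se, freq, used_n, bad = gwas_per_variant(X, y, counts, int(seed))
    freq = np.where((freq > 0) & (freq < 1), freq, np.nan)  # missing policy
    df = _variant_frame(freq, used_n, pos_bp, pos_cm, chrom, beta, se, info)
    return ss.SumStats(df, n_total=n, trait_type="quantitative",
                       var_y=float(np.var(y, ddof=1)))


def _hardcall_probs(dosages: DosagePanel, j: int) -> np.ndarray:
    """P(G = g | signal) for one variant under the dosage construction:
    HWE prior at the panel frequency times the Gaussian channel likelihood.
    Degenerates to the true genotype when INFO = 1 (no channel noise)."""
    s = np.asarray(dosages.signal[:, j], dtype=np.float64)
    f = float(dosages.panel_freq[j])
    sd = float(dosages.noise_sd[j])
    prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    if sd < 1e-12:
        probs = np.zeros((s.shape[0], 3))
        g = np.clip(np.rint(s).astype(np.int64), 0, 2)
        probs[np.arange(s.shape[0]), g] = 1.0
        return probs
    z = (s[:, None] - np.arange(3)[None, :]) / sd
    like = np.exp(-0.5 * z**2)
    post = like * prior[None, :]
    tot = post.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return post / tot


def run_gwas_multiple_imputation(
    panel: GenotypePanel,
    dosages: DosagePanel,
    y: np.ndarray,
    n_imputations: int = 20,
    seed: int = 0,
) -> "ss.SumStats":
    """GWAS by multiple imputation: sample hard calls from the per-genotype
    probabilities implied by the dosage construction, run a GWAS per
    imputation, and pool by Rubin's rules (mean of estimates; total variance
    = within + (1 + 1/m) * between)."""
    if n_imputations < 2:
        raise ValueError("need at least 2 imputations")
    if dosages.panel_freq is None or dosages.signal is None:
        raise ValueError("dosage panel lacks construction parameters")
    n, m = dosages.dosages.shape
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    # per-variant genotype probabilities, sampled n_imputations times
    betas = np.empty((n_imputations, m))
    ses = np.empty((n_imputations, m))
    counts = np.full(m, n, dtype=np.int64)
    for t in range(n_imputations):
        H = np.empty((n, m), dtype=np.int8)
        for j in range(m):
            probs = _hardcall_probs(dosages, j)
            if np.any(~np.isfinite(probs)):
                raise ValueError(f"degenerate genotype probabilities at variant {j}")
            u = rng.random(n)
            c = probs.cumsum(axis=1)
            H[:, j] = (u[:, None] > c[:, :2]).sum(axis=1)
        b, s, _, _, _ = gwas_per_variant(H, y, counts,
                                         int(rng.integers(0, 2**31 - 1)))
        betas[t] = b
        ses[t] = s
    pooled = betas.mean(axis=0)
    within = (ses**2).mean(axis=0)
    between = betas.var(axis=0, ddof=1)
    total_var = within + (1.0 + 1.0 / n_imputations) * between
    df = _variant_frame(dosages.freq, counts, dosages.pos_bp, dosages.pos_cm,
                        dosages.chrom, pooled, np.sqrt(total_var),
                        dosages.realized_info)
    return ss.SumStats(df, n_total=n, trait_type="quantitative",
                       var_y=float(np.var(y, ddof=1)))


_SCENARIOS = ("sample-size", "dosage", "ld-mismatch")

# Conditions of the three study scenarios; see docs/methods.md for rationale.
_SCENARIO_DEFAULTS = dict(
    n_individuals=2_000,
    n_variants=1_000,
    h2=0.2,
    n_causal_frac=0.05,
    maf_range=(0.01, 0.5),
    ld_decay=1.5,
    n_founders=8,
    genetic_map="hotspot",
    spacing_cm=0.05,
    fractions=(1.0, 0.8, 0.6),
    proportions=(0.5, 0.25, 0.25),
    info_range=(0.3, 1.0),
    drift=0.02,
    n_ld_individuals=None,
)


def assign_subsample_fractions(m, fractions, proportions, rng):
    """Exact largest-remainder counts per group, shuffled assignment."""
    props = np.asarray(proportions, dtype=np.float64)
    raw = props * m
    counts = np.floor(raw).astype(np.int64)
    rem = m - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    per_variant = np.repeat(np.asarray(fractions, dtype=np.float64), counts)
    rng.shuffle(per_variant)
    return per_variant


def drift_founders(founders: np.ndarray, freq: np.ndarray, drift: float,
                   rng) -> np.ndarray:
    """Resample each founder allele from Bernoulli(freq) with probability
    ``drift``; drift 0 returns an identical pool (exchangeable panels)."""
    out = founders.copy()
    if drift <= 0:
        return out
    mask = rng.random(out.shape) < drift
    redraw = (rng.random(out.shape) < freq[None, :]).astype(np.int8)
    out[mask] = redraw[mask]
    return out


def build_scenario(name: str, params: dict | None = None, seed: int = 0) -> SimScenario:
    """Generate a full misspecification scenario.

    - ``sample-size``: per-variant GWAS subsampling at fractions (1.0, 0.8,
      0.6) in proportions (1/2, 1/4, 1/4).
    - ``dosage``: GWAS on imputed dosages with heterogeneous INFO drawn
      uniformly from ``info_range``; LD reference panel keeps the true
      genotypes.
    - ``ld-mismatch``: a second panel is drawn from a drifted copy of the
      founder pool (drift = per-allele resampling probability); drift 0 makes
      the two panels exchangeable.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
    cfg = dict(_SCENARIO_DEFAULTS)
    cfg.update(params or {})
    rng = np.random.default_rng(seed)
    s_panel, s_pheno, s_gwas, s_extra = (int(x) for x in
                                         rng.integers(0, 2**31 - 1, size=4))
    n, m = cfg["n_individuals"], cfg["n_variants"]
    panel = simulate_genotypes(
        n, m,
        maf_range=cfg["maf_range"],
        ld_decay=cfg["ld_decay"],
        n_founder_haplotypes=cfg["n_founders"],
        seed=s_panel,
        spacing_cm=cfg["spacing_cm"],
        genetic_map=cfg["genetic_map"],
    )
    n_causal = max(1, int(round(cfg["n_causal_frac"] * m)))
    pheno = simulate_phenotype(panel, cfg["h2"], n_causal, seed=s_pheno)

    fractions = None
    dosages = None
    ld_panel = None
    if name == "sample-size":
        fractions = assign_subsample_fractions(m, cfg["fractions"], cfg["proportions"],
                                      np.random.default_rng(s_extra))
        gwas = run_gwas_linear(panel, pheno.y, fractions, seed=s_gwas)
    elif name == "dosage":
        info = np.random.default_rng(s_extra).uniform(*cfg["info_range"], size=m)
        dosages = simulate_dosages(panel, info, seed=s_extra)
        gwas = run_gwas_linear(dosages, pheno.y, 1.0, seed=s_gwas)
    else:  # ld-mismatch
        gwas = run_gwas_linear(panel, pheno.y, 1.0, seed=s_gwas)
        rng2 = np.random.default_rng(s_extra)
        alt_founders = drift_founders(panel.founders, panel.freq, cfg["drift"],
                                      rng2)
        n_ld = cfg["n_ld_individuals"] or n
        ld_panel = simulate_genotypes(
            n_ld, m,
            maf_range=cfg["maf_range"],
            ld_decay=cfg["ld_decay"],
            seed=int(rng2.integers(0, 2**31 - 1)),
            genetic_map=panel.pos_cm,  # the alternative panel shares the map
            _founder_pool=alt_founders,
        )
    return SimScenario(
        name=name,
        panel=panel,
        pheno=pheno,
        gwas=gwas,
        seed=seed,
        subsample_fractions=fractions,
        dosages=dosages,
        ld_panel=ld_panel,
        params=cfg,
    )
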