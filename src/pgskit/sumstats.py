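"""The summary-statistics data model and per-variant formulas.

The whole toolkit rests on one identity: for a quantitative trait analyzed
with linear regression,

    sd(G_j) ~= sd(y) / sqrt(n_j se(gamma_j)^2 + gamma_j^2)

and its binary-trait analogue with sd(y) replaced by 2 and n by the effective
sample size n_eff = 4 / (1/n_cases + 1/n_controls).  Everything else here is
algebra on that identity: inferring genotype sds from reported statistics,
imputing per-variant sample sizes by inverting it, converting per-allele
effects to the dimensionless marginal-correlation scale, and correcting
dosage-based statistics with imputation INFO scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SumStats",
    "ScaledStats",
    "InfoCorrection",
    "INFO_CORRECTIONS",
    "read_sumstats",
    "sd_from_sumstats",
    "sd_from_af",
    "estimate_var_y",
    "impute_n",
    "effective_sample_size",
    "scaled_effects",
    "per_allele_effects",
    "apply_info_correction",
    "estimate_power_ratio",
    "global_neff_percentile",
    "recompute_info",
]

REQUIRED_COLUMNS = ("chr", "pos", "a0", "a1", "beta", "beta_se")


@dataclass
class SumStats:
    """Per-variant GWAS results plus study-level metadata.

    ``df`` must contain chr, pos, a0, a1, beta, beta_se; optional columns are
    freq, info, n (quantitative) or n_eff (binary), n_cases, n_controls.
    Binary traits are handled on the effective-n scale throughout: ``n``
    returns n_eff for binary traits.
    """

    df: pd.DataFrame
    n_total: float | None = None
    trait_type: str = "quantitative"
    n_cases: float | None = None
    n_controls: float | None = None
    var_y: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be quantitative or binary")
        se = self.df["beta_se"].to_numpy(dtype=float)
        if np.any(se[np.isfinite(se)] < 0):
            raise ValueError("beta_se must be non-negative")
        if "freq" in self.df.columns:
            f = self.df["freq"].to_numpy(dtype=float)
            ok = np.isfinite(f)
            if np.any((f[ok] <= 0) | (f[ok] >= 1)):
                raise ValueError("freq must lie strictly in (0, 1)")
        if "info" in self.df.columns:
            i = self.df["info"].to_numpy(dtype=float)
            ok = np.isfinite(i)
            if np.any((i[ok] <= 0) | (i[ok] > 1.0 + 1e-9)):
                raise ValueError("info must lie in (0, 1]")
        same = self.df["a0"].astype(str) == self.df["a1"].astype(str)
        if same.any():
            raise ValueError("a0 and a1 must differ for every variant")
        if self.trait_type == "binary" and "n_eff" not in self.df.columns:
            if self.n_cases is not None and self.n_controls is not None:
                self.df = self.df.copy()
                self.df["n_eff"] = effective_sample_size(self.n_cases,
                                                         self.n_controls)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> np.ndarray:
        """Per-variant sample size (effective n for binary traits)."""
        col = "n_eff" if self.trait_type == "binary" else "n"
        if col not in self.df.columns:
            if self.n_total is None:
                raise ValueError(f"no per-variant {col} and no n_total")
            return np.full(len(self.df), float(self.n_total))
        return self.df[col].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def with_df(self, df: pd.DataFrame, **meta) -> "SumStats":
        out = replace(self, df=df)
        out.meta = {**self.meta, **meta}
        return out

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


#: header synonyms understood by :func:`read_sumstats`
DEFAULT_COLUMN_MAP = {
    "chr": ["chr", "chrom", "chromosome", "#chr"],
    "pos": ["pos", "bp", "position", "pos_bp"],
    "a0": ["a0", "ref", "allele0", "other_allele", "a2"],
    "a1": ["a1", "alt", "allele1", "effect_allele"],
    "beta": ["beta", "effect", "b"],
    "beta_se": ["beta_se", "se", "standard_error"],
    "freq": ["freq", "af", "eaf", "maf", "freq1"],
    "info": ["info", "rsq", "r2", "imputation_quality"],
    "n": ["n", "n_total", "samplesize"],
    "n_eff": ["n_eff", "neff", "effective_n"],
    "n_cases": ["n_cases", "ncase", "cases"],
    "n_controls": ["n_controls", "ncontrol", "controls"],
}


def read_sumstats(path, column_map: dict | None = None,
                  trait_type: str = "quantitative",
                  n_total: float | None = None, **kwargs) -> SumStats:
    """Read a summary-statistics TSV, translating external headers.

    ``column_map`` maps canonical names to the file's header names; headers
    not covered fall back to the built-in synonym table.
    """
    df = pd.read_csv(path, sep="\t", **kwargs)
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, synonyms in DEFAULT_COLUMN_MAP.items():
        if column_map and canon in column_map:
            src = column_map[canon]
            if src not in df.columns:
                raise ValueError(
                    f"mapped column {src!r} not found; available: {list(df.columns)}")
            rename[src] = canon
            continue
        for s in synonyms:
            if s in lower:
                rename[lower[s]] = canon
                break
    df = df.rename(columns=rename)
    return SumStats(df, n_total=n_total, trait_type=trait_type)


def sd_from_sumstats(stats: SumStats, sd_y: float | None = None) -> np.ndarray:
    """Genotype sd inferred from (beta, se, n): sd(y)/sqrt(n se^2 + beta^2)
    for quantitative traits, 2/sqrt(n_eff se^2 + beta^2) for binary traits."""
    beta = stats.column("beta")
    se = stats.column("beta_se")
    n = stats.n
    if stats.trait_type == "binary":
        num = 2.0
    else:
        if sd_y is None:
            if stats.var_y is not None:
                sd_y = float(np.sqrt(stats.var_y))
            else:
                sd_y = float(np.sqrt(estimate_var_y(stats)))
        num = sd_y
    denom2 = n * se**2 + beta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom2 > 0, num / np.sqrt(denom2), np.nan)
    n_missing = int(np.sum(~np.isfinite(out)))
    if n_missing:
        logger.info("sd_from_sumstats: %d variants with missing output", n_missing)
    return out


def sd_from_af(f: np.ndarray, info: np.ndarray | None = None) -> np.ndarray:
    """Genotype sd expected under HWE from the allele frequency,
    sqrt(2 f (1-f) INFO); INFO defaults to 1."""
    f = np.asarray(f, dtype=float)
    if info is None:
        info = 1.0
    info = np.broadcast_to(np.asarray(info, dtype=float), f.shape)
    with np.errstate(invalid="ignore"):
        out = np.where((f > 0) & (f < 1), np.sqrt(2.0 * f * (1.0 - f) * info),
                       np.nan)
    return out


def estimate_var_y(stats: SumStats) -> float:
    """Phenotypic variance estimated as the 1st percentile over variants of
    0.5 (N se^2 + beta^2); the percentile approximates the minimum (reached
    near f = 0.5) while staying robust to outliers."""
    if stats.trait_type == "binary":
        raise ValueError("var(y) is not needed for binary traits; "
                         "use the effective-n path (the constant 2 replaces "
                         "sd(y))")
    if stats.n_total is None:
        raise ValueError("n_total required to estimate var(y)")
    beta = stats.column("beta")
    se = stats.column("beta_se")
    vals = 0.5 * (stats.n_total * se**2 + beta**2)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no usable variants")
    if vals.size < 100:
        logger.warning("estimate_var_y: only %d variants; the percentile "
                       "heuristic is recommended with >= 100", vals.size)
    return float(np.percentile(vals, 1.0))


def impute_n(stats: SumStats, var_y: float | None = None,
             clamp: tuple[float, float] | None = (0.5, 1.1),
             info: np.ndarray | None = None) -> pd.DataFrame:
    """Impute per-variant (effective) sample sizes by inverting the sd
    identity: n = (var(y)/var(G) - beta^2)/se^2, with var(G) = 2 f (1-f) INFO.

    Returns a DataFrame with columns ``n_imputed`` (clamped), ``n_raw`` and
    ``clamped``.  Clamp bounds are fractions of n_total, default [0.5, 1.1].
    """
    beta = stats.column("beta")
    se = stats.column("beta_se")
    if "freq" not in stats.df.columns:
        raise ValueError("allele frequencies required to impute n")
    f = stats.column("freq")
    if info is None and "info" in stats.df.columns:
        info = stats.column("info")
    var_g = sd_from_af(f, info) ** 2
    if stats.trait_type == "binary":
        num = 4.0
    else:
        if var_y is None:
            var_y = stats.var_y if stats.var_y is not None else estimate_var_y(stats)
        num = float(var_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((var_g > 0) & (se > 0),
                       (num / var_g - beta**2) / se**2, np.nan)
    clamped_flag = np.zeros(raw.shape, dtype=bool)
    out = raw.copy()
    if clamp is not None:
        if stats.n_total is None:
            raise ValueError("n_total required for clamping")
        lo, hi = clamp[0] * stats.n_total, clamp[1] * stats.n_total
        clamped_flag = np.isfinite(raw) & ((raw < lo) | (raw > hi))
        out = np.clip(raw, lo, hi)
    return pd.DataFrame({"n_imputed": out, "n_raw": raw, "clamped": clamped_flag})


def effective_sample_size(n_cases, n_controls) -> float:
    """Effective sample size 4/(1/n_cases + 1/n_controls) per study, defined
    as 0 when either count is 0 (continuity limit); a meta-analysis passes
    per-study arrays and gets the sum of per-study values."""
    cases = np.atleast_1d(np.asarray(n_cases, dtype=float))
    controls = np.atleast_1d(np.asarray(n_controls, dtype=float))
    if cases.shape != controls.shape:
        raise ValueError("case and control counts must align")
    if np.any(cases < 0) or np.any(controls < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        per_study = np.where((cases > 0) & (controls > 0),
                             4.0 / (1.0 / np.where(cases > 0, cases, 1.0)
                                    + 1.0 / np.where(controls > 0, controls, 1.0)),
                             0.0)
    return float(per_study.sum())


@dataclass
class ScaledStats:
    """Marginal effects on the correlation (standardized) scale."""

    beta_scaled: np.ndarray
    z: np.ndarray
    sd_ss: np.ndarray
    var_y: float
    n: np.ndarray


def scaled_effects(stats: SumStats, var_y: float | None = None) -> ScaledStats:
    """Convert per-allele effects to the dimensionless marginal-correlation
    scale: beta_scaled = gamma / sqrt(n se^2 + gamma^2) = Z / sqrt(n + Z^2)."""
    beta = stats.column("beta")
    se = stats.column("beta_se")
    n = stats.n
    if stats.trait_type == "binary":
        vy = 4.0
    elif var_y is not None:
        vy = float(var_y)
    elif stats.var_y is not None:
        vy = float(stats.var_y)
    else:
        vy = estimate_var_y(stats)
    denom2 = n * se**2 + beta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(denom2 > 0, beta / np.sqrt(denom2), np.nan)
        z = np.where(se > 0, beta / se, np.nan)
        sd_ss = np.where(denom2 > 0, np.sqrt(vy / denom2), np.nan)
    return ScaledStats(beta_scaled=scaled, z=z, sd_ss=sd_ss, var_y=vy, n=n)


def per_allele_effects(beta_scaled: np.ndarray, scaled: ScaledStats) -> np.ndarray:
    """Map scaled effects back to trait units per allele:
    gamma = beta_scaled * sd(y) / sd(G).  Exact inverse of scaled_effects on
    the same statistics."""
    return np.asarray(beta_scaled) * np.sqrt(scaled.var_y) / scaled.sd_ss


@dataclass(frozen=True)
class InfoCorrection:
    """An INFO-based correction: gamma *= INFO^a_gamma, se *= INFO^a_se,
    n *= INFO^a_n.  The named presets are configuration, not code."""

    name: str
    a_gamma: float
    a_se: float
    a_n: float

    def __post_init__(self):
        for a in (self.a_gamma, self.a_se, self.a_n):
            if not (0.0 <= a <= 1.0):
                raise ValueError("exponents must lie in [0, 1]")


INFO_CORRECTIONS = {
    "sqrt_info": InfoCorrection("sqrt_info", 0.5, 0.5, 0.0),
    "info": InfoCorrection("info", 1.0, 0.0, 1.0),
    "in_between": InfoCorrection("in_between", 1.0, 0.5, 1.0),
}


def apply_info_correction(stats: SumStats, correction) -> SumStats:
    """Return a corrected copy of the statistics.

    ``sqrt_info`` multiplies gamma and se by sqrt(INFO) (preserving Z);
    ``info`` multiplies gamma by INFO and n by INFO (preserving se);
    ``in_between`` multiplies gamma by INFO, se by sqrt(INFO) and n by INFO.
    """
    if isinstance(correction, str):
        try:
            correction = INFO_CORRECTIONS[correction]
        except KeyError:
            raise ValueError(
                f"unknown correction {correction!r}; "
                f"available: {sorted(INFO_CORRECTIONS)}") from None
    if "info" in stats.df.columns:
        info = stats.column("info")
    else:
        logger.warning("apply_info_correction: no INFO column; assuming 1")
        info = np.ones(len(stats))
    df = stats.df.copy()
    df["beta"] = df["beta"].to_numpy(dtype=float) * info**correction.a_gamma
    df["beta_se"] = df["beta_se"].to_numpy(dtype=float) * info**correction.a_se
    ncol = "n_eff" if stats.trait_type == "binary" else "n"
    if correction.a_n > 0 and ncol in df.columns:
        df[ncol] = df[ncol].to_numpy(dtype=float) * info**correction.a_n
    return stats.with_df(df, info_correction=correction.name)


def estimate_power_ratio(chi2_boosted: np.ndarray, chi2_linear: np.ndarray,
                         significant_mask: np.ndarray,
                         summary: str = "mean_of_ratios"):
    """Multiplicative chi-square boost over genome-wide significant variants,
    interpreted as the increase in effective sample size.

    Returns (value, diagnostics) where diagnostics reports both the mean of
    per-variant ratios and the ratio of means.
    """
    b = np.asarray(chi2_boosted, dtype=float)
    l = np.asarray(chi2_linear, dtype=float)
    mask = np.asarray(significant_mask, dtype=bool)
    if b.shape != l.shape or b.shape != mask.shape:
        raise ValueError("inputs must be aligned")
    if not mask.any():
        raise ValueError("no variants selected")
    bs, ls = b[mask], l[mask]
    mean_of_ratios = float(np.mean(bs / ls))
    ratio_of_means = float(np.mean(bs) / np.mean(ls))
    diagnostics = {"mean_of_ratios": mean_of_ratios,
                   "ratio_of_means": ratio_of_means,
                   "n_selected": int(mask.sum())}
    if summary not in diagnostics:
        raise ValueError("summary must be mean_of_ratios or ratio_of_means")
    return diagnostics[summary], diagnostics


def global_neff_percentile(imputed_neff: np.ndarray, percentile: float = 80.0,
                           reported_neff: float | None = None):
    """Global effective sample size as a percentile (default 80th, linear
    interpolation between order statistics) of unclamped imputed values; if a
    reported case/control-based value is supplied, also return the ratio."""
    v = np.asarray(imputed_neff, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty input")
    est = float(np.percentile(v, percentile))
    if reported_neff is not None:
        return est, est / float(reported_neff)
    return est


def recompute_info(dosages) -> np.ndarray:
    """MACH-style INFO recomputed from a dosage matrix:
    var(D_j) / (2 f_j (1 - f_j)) with f_j = mean(D_j)/2, clipped to (0, 1].
    Monomorphic columns yield NaN (flagged missing, not 0)."""
    D = dosages.dosages if hasattr(dosages, "dosages") else np.asarray(dosages)
    if D.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    f = D.mean(axis=0) / 2.0
    denom = 2.0 * f * (1.0 - f)
    var = D.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.where((denom > 0) & (var > 0), var / denom, np.nan)
    return np.clip(info, None, 1.0)
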