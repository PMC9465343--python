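"""Variant-level quality control of GWAS summary statistics.

Two layers, mirroring common practice with external summary statistics:

- "qc1": compare the genotype sd inferred from the summary statistics
  (sd_ss, INFO-adjusted when INFO is available) with the sd expected from
  the reported allele frequency (sd_af = sqrt(2 f (1-f))).  A variant whose
  sd_ss is far below sd_af typically has an overstated sample size or poor
  imputation; the rule also ends up filtering very rare variants through the
  sd_af arm.
- "qc2": extended filters — minimum INFO, allele-frequency agreement with a
  reference panel, exclusion of long-range LD regions (chr6:25-33.5 Mbp and
  chr8:8-12 Mbp by default), a per-variant sample size floor relative to the
  maximum, and a MAF floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

__all__ = [
    "QCThresholds",
    "QCReport",
    "match_alleles",
    "qc_sd_filter",
    "qc_extended",
    "qc_plot_data",
    "DEFAULT_EXCLUDED_REGIONS",
]

#: two known long-range LD regions (chr, start, end), 1-based inclusive
DEFAULT_EXCLUDED_REGIONS = (("6", 25_000_000, 33_500_000),
                            ("8", 8_000_000, 12_000_000))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QCThresholds:
    info_min: float = 0.4
    maf_min: float = 0.01
    freq_diff_max: float = 0.1
    n_frac_min: float = 0.7
    # sd-outlier rule constants (from prior work; configuration, not code)
    sd_ratio_min: float = 0.5
    sd_diff_max: float = 0.1
    sd_ss_min: float = 0.1
    sd_af_min: float = 0.05
    excluded_regions: tuple = DEFAULT_EXCLUDED_REGIONS

    def __post_init__(self):
        if not (0 <= self.info_min <= 1):
            raise ValueError("info_min must lie in [0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.freq_diff_max < 0 or self.n_frac_min < 0 or self.n_frac_min > 1:
            raise ValueError("invalid thresholds")
        for region in self.excluded_regions:
            chrom, start, end = region
            if start > end:
                raise ValueError(f"malformed region {region}")


@dataclass
class QCReport:
    """Per-variant flags plus counts; flags are pure functions of inputs."""

    flags: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        return {c: int(self.flags[c].sum()) for c in self.flags.columns
                if self.flags[c].dtype == bool}

    def removed_mask(self) -> np.ndarray:
        """Union of all removal flags (columns starting with a flag name)."""
        cols = [c for c in self.flags.columns if self.flags[c].dtype == bool
                and c not in ("matched", "allele_flipped")]
        if not cols:
            return np.zeros(len(self.flags), dtype=bool)
        return self.flags[cols].to_numpy().any(axis=1)

    def write(self, prefix: str) -> None:
        self.flags.to_csv(prefix + ".tsv", sep="\t", index=False)
        with open(prefix + ".json", "w") as fh:
            json.dump({"counts": self.counts, "thresholds": self.thresholds},
                      fh, indent=2)


def _check_duplicates(df: pd.DataFrame, label: str) -> None:
    dup = df.duplicated(subset=["chr", "pos"], keep=False)
    if dup.any():
        listing = df.loc[dup, ["chr", "pos"]].drop_duplicates().to_records(index=False)
        raise ValueError(f"duplicated positions in {label}: {list(listing)[:20]}")


def match_alleles(stats: SumStats, reference: pd.DataFrame,
                  keep_ambiguous: bool = False):
    """Align summary statistics to a reference variant table on (chr, pos).

    Swapped alleles are flipped (beta negated, freq mirrored) and flagged;
    palindromic A/T and C/G variants are flagged strand-ambiguous and removed
    unless ``keep_ambiguous``; unmatched or allele-incompatible variants are
    dropped with counts.  Returns (aligned SumStats, QCReport).
    """
    df = stats.df.copy().reset_index(drop=True)
    ref = reference.copy().reset_index(drop=True)
    _check_duplicates(df, "summary statistics")
    _check_duplicates(ref, "reference")
    df["chr"] = df["chr"].astype(str)
    ref["chr"] = ref["chr"].astype(str)
    merged = df.merge(ref[["chr", "pos", "a0", "a1"]
                          + (["freq"] if "freq" in ref.columns else [])],
                      on=["chr", "pos"], how="left", suffixes=("", "_ref"))
    has_ref = merged["a0_ref"].notna().to_numpy()
    a0 = merged["a0"].astype(str).str.upper().to_numpy()
    a1 = merged["a1"].astype(str).str.upper().to_numpy()
    r0 = merged["a0_ref"].astype(str).str.upper().to_numpy()
    r1 = merged["a1_ref"].astype(str).str.upper().to_numpy()
    same = has_ref & (a0 == r0) & (a1 == r1)
    flipped = has_ref & (a0 == r1) & (a1 == r0) & ~same
    ambiguous = np.array([_COMPLEMENT.get(x) == y for x, y in zip(a0, a1)])
    matched = same | flipped
    incompatible = has_ref & ~matched

    out = merged.loc[:, df.columns].copy()
    if flipped.any():
        out.loc[flipped, "beta"] = -out.loc[flipped, "beta"]
        if "freq" in out.columns:
            out.loc[flipped, "freq"] = 1.0 - out.loc[flipped, "freq"]
        out.loc[flipped, ["a0", "a1"]] = merged.loc[flipped,
                                                    ["a0_ref", "a1_ref"]].to_numpy()
    flags = pd.DataFrame({
        "chr": merged["chr"],
        "pos": merged["pos"],
        "matched": matched,
        "allele_flipped": flipped,
        "strand_ambiguous": ambiguous,
        "unmatched": ~has_ref,
        "allele_incompatible": incompatible,
    })
    keep = matched & (keep_ambiguous | ~ambiguous)
    aligned = stats.with_df(out.loc[keep].reset_index(drop=True),
                            allele_matching="chr+pos")
    report = QCReport(flags=flags,
                      thresholds={"keep_ambiguous": keep_ambiguous})
    return aligned, report


def qc_sd_filter(sd_af: np.ndarray, sd_ss: np.ndarray,
                 thresholds: QCThresholds | None = None) -> QCReport:
    """The sd-comparison outlier rule ("qc1").

    Flags variant j when sd_ss < 0.5 sd_af, or sd_ss > sd_af + 0.1, or
    sd_ss < 0.1, or sd_af < 0.05 (constants configurable).  The caller is
    expected to pass sd_ss already divided by sqrt(INFO) when INFO is
    available (equivalently sd_af multiplied by sqrt(INFO)).
    """
    t = thresholds or QCThresholds()
    sd_af = np.asarray(sd_af, dtype=float)
    sd_ss = np.asarray(sd_ss, dtype=float)
    if sd_af.shape != sd_ss.shape:
        raise ValueError("sd vectors must align")
    low_ratio = sd_ss < t.sd_ratio_min * sd_af
    high_diff = sd_ss > sd_af + t.sd_diff_max
    low_ss = sd_ss < t.sd_ss_min
    low_af = sd_af < t.sd_af_min
    outlier = low_ratio | high_diff | low_ss | low_af
    flags = pd.DataFrame({
        "sd_outlier": outlier,
        "sd_low_ratio": low_ratio,
        "sd_high_diff": high_diff,
        "sd_ss_too_small": low_ss,
        "sd_af_too_small": low_af,
    })
    return QCReport(flags=flags, thresholds={
        "sd_ratio_min": t.sd_ratio_min, "sd_diff_max": t.sd_diff_max,
        "sd_ss_min": t.sd_ss_min, "sd_af_min": t.sd_af_min},
        extra={"sd_af": sd_af, "sd_ss": sd_ss})


def _in_regions(chrom: np.ndarray, pos: np.ndarray, regions) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for rc, start, end in regions:
        hit |= (chrom == str(rc)) & (pos >= start) & (pos <= end)
    return hit


def qc_extended(stats: SumStats, ref_freq: np.ndarray | None = None,
                thresholds: QCThresholds | None = None) -> QCReport:
    """The extended filters ("qc2"), each recorded separately:
    INFO >= info_min; |f_stats - f_ref| <= freq_diff_max; position outside
    the excluded long-range LD regions; n_j >= n_frac_min * max(n); and
    MAF >= maf_min."""
    t = thresholds or QCThresholds()
    m = len(stats)
    chrom = stats.df["chr"].astype(str).to_numpy()
    pos = stats.df["pos"].to_numpy()

    low_info = np.zeros(m, dtype=bool)
    if "info" in stats.df.columns:
        low_info = stats.column("info") < t.info_min

    freq_mismatch = np.zeros(m, dtype=bool)
    if ref_freq is not None and "freq" in stats.df.columns:
        ref_freq = np.asarray(ref_freq, dtype=float)
        freq_mismatch = np.abs(stats.column("freq") - ref_freq) > t.freq_diff_max

    in_region = _in_regions(chrom, pos, t.excluded_regions)

    low_n = np.zeros(m, dtype=bool)
    try:
        n = stats.n
        low_n = n < t.n_frac_min * np.nanmax(n)
    except ValueError:
        pass

    low_maf = np.zeros(m, dtype=bool)
    if "freq" in stats.df.columns:
        f = stats.column("freq")
        low_maf = np.minimum(f, 1 - f) < t.maf_min

    flags = pd.DataFrame({
        "low_info": low_info,
        "freq_mismatch": freq_mismatch,
        "in_excluded_region": in_region,
        "low_n": low_n,
        "low_maf": low_maf,
    })
    return QCReport(flags=flags, thresholds={
        "info_min": t.info_min, "freq_diff_max": t.freq_diff_max,
        "n_frac_min": t.n_frac_min, "maf_min": t.maf_min,
        "excluded_regions": [list(r) for r in t.excluded_regions]})


def _slope_through_origin(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        return np.nan
    return float((x[ok] @ y[ok]) / (x[ok] @ x[ok]))


def qc_plot_data(sd_af: np.ndarray, sd_ss: np.ndarray,
                 info: np.ndarray | None = None,
                 thresholds: QCThresholds | None = None):
    """Plot-ready table of (sd_af, sd_ss_raw, sd_ss_info_adjusted, flag)
    plus the two regression slopes (through the origin).  The INFO
    adjustment divides sd_ss by sqrt(INFO)."""
    sd_af = np.asarray(sd_af, dtype=float)
    sd_ss = np.asarray(sd_ss, dtype=float)
    if info is None:
        info = np.ones_like(sd_af)
    info = np.asarray(info, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = sd_ss / np.sqrt(info)
    if sd_af.size == 0:
        table = pd.DataFrame(columns=["sd_af", "sd_ss_raw",
                                      "sd_ss_info_adjusted", "sd_outlier"])
        return table, {"slope_raw": np.nan, "slope_adjusted": np.nan}
    report = qc_sd_filter(sd_af, adj, thresholds)
    table = pd.DataFrame({
        "sd_af": sd_af,
        "sd_ss_raw": sd_ss,
        "sd_ss_info_adjusted": adj,
        "sd_outlier": report.flags["sd_outlier"].to_numpy(),
    })
    slopes = {"slope_raw": _slope_through_origin(sd_af, sd_ss),
              "slope_adjusted": _slope_through_origin(sd_af, adj)}
    return table, slopes
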