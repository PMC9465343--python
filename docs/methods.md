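# Methods

## The problem

Polygenic scores (PGS) are built from GWAS summary statistics — per-variant
marginal effects γ̂_j, standard errors se(γ̂_j), sample sizes n_j and
metadata — combined with a linkage-disequilibrium (LD) reference panel. In
practice these inputs are misspecified in recurring ways: per-variant sample
sizes differ across variants (meta-analyses of cohorts with different
chips), effect sizes and standard errors computed from imputed allele
dosages are distorted relative to true genotypes, INFO scores and allele
frequencies are reported for the wrong cohort, and the LD reference comes
from a different population. `pgskit` implements (i) formulas to detect and
correct these misspecifications, (ii) two PGS solvers — a summary-statistics
elastic net (lassosum2) and a spike-and-slab Gibbs sampler (the LDpred2
family) — with robustness options targeted at misspecification, and (iii) a
synthetic-data module that generates all three misspecification regimes so
that every claim in this package is testable without external downloads.

## The central identity

For a quantitative trait analyzed by per-variant linear regression,

    sd(G_j) ≈ sd(y) / sqrt(n_j · se(γ̂_j)² + γ̂_j²),

and for a binary trait analyzed by logistic regression the same identity
holds with sd(y) replaced by 2 and n_j by the effective sample size
n_eff = 4/(1/n_cases + 1/n_controls). Everything in `pgskit.sumstats` is
algebra on this identity:

- `sd_from_sumstats` evaluates it directly; `sd_from_af` gives the
  HWE-expected sd `sqrt(2 f (1−f) · INFO)` from the reported allele
  frequency. Comparing the two per variant is the QC backbone ("qc1"):
  a variant whose summary-statistics sd is far below its frequency-implied
  sd typically carries an overstated n or poor imputation.
- `impute_n` inverts the identity: n̂_j = (var(y)/var(G_j) − γ̂_j²)/se_j²
  (effective-n analogue with 4 in place of var(y)). Estimates are bounded to
  [0.5 N, 1.1 N] by default, with a flag recording which were clamped.
- var(y) is estimated as the 1st percentile over variants of
  0.5·(N se_j² + γ̂_j²); the percentile approximates the minimum (attained
  near f = 0.5) while ignoring outliers. Percentiles use numpy's linear
  interpolation between order statistics throughout the package.
- `scaled_effects` maps per-allele effects to the dimensionless
  marginal-correlation scale β̂_j = γ̂_j / sqrt(n_j se_j² + γ̂_j²)
  (= Z/sqrt(n + Z²)); `per_allele_effects` is its exact inverse.

## Imputed dosages and INFO corrections

A posterior-mean dosage D_j has var(D_j) = INFO_j · var(G_j) (the MACH
measure), so dosage-based statistics satisfy sd(D) = sd(G)·√INFO and
se_imp ≈ se_true/√INFO. Three correction presets are shipped as
configuration (name → exponent triple applied as γ̂·INFO^a_γ, se·INFO^a_se,
n·INFO^a_n):

| name       | a_γ | a_se | a_n | preserved quantity |
|------------|-----|------|-----|--------------------|
| sqrt_info  | ½   | ½    | 0   | Z-scores           |
| info       | 1   | 0    | 1   | standard errors    |
| in_between | 1   | ½    | 1   | —                  |

`sqrt_info` leaves the scaled effects β̂ unchanged and is equivalent to
post-multiplying the final per-allele PGS weights by √INFO, which
down-weights noisily estimated low-INFO variants; it is the default
recommendation. `recompute_info` recovers the MACH INFO from a dosage
matrix, and the QC plot compares sd_ss/√INFO against sd_af.

## PGS solvers

**lassosum2** minimizes ½βᵀRβ − β̂ᵀβ + ½δΣq_jβ_j² + λΣq_j|β_j| over scaled
effects, by cyclic coordinate descent: β_j ← S(u_j, λq_j)/(1 + δq_j) with
u_j = β̂_j − (Rβ)_j + β_j. The rotated residual Rβ is cached and updated
incrementally, touching only the stored neighbors of a coordinate that
changed. Per-variant penalty factors q_j = max_k(n_k)/n_j penalize variants
with smaller GWAS sample sizes. Defaults: 30 λ values log-spaced in
[λ₀/100, λ₀] with λ₀ = max|β̂| (the smallest λ with an all-zero solution),
δ ∈ {0.001, 0.01, 0.1, 1}. Convergence: max absolute coefficient change
below 10⁻⁵·λ₀, at most 500 sweeps, fixed ascending sweep order; a fit whose
max|β| exceeds 5 is flagged divergent (scaled effects are correlations, so
5 is far outside the valid region) and the path restarts cold.

**LDpred2 family.** The model is β̂ ~ N(Rβ, R/n) with the spike-and-slab
prior β_j ~ N(0, h²/(M p)) w.p. p, else 0. Conditional updates: with
σ² = h²/(Mp) and residual u_j = β̂_j − c·((Rβ)_j − β_j), the inclusion
probability is 1/(1 + ((1−p)/p)·√(1+n_jσ²)·exp(−½u_j²n_j·(n_jσ²)/(1+n_jσ²)))
and an included effect is drawn from N(u_j·n_jσ²/(1+n_jσ²), σ²/(1+n_jσ²)).

- `fit_inf` is the p = 1 closed form (R + M/(n h²) I)⁻¹β̂, solved per LD
  block.
- grid mode fixes (p, h²); `build_h2_grid` anchors h² to the LD-score
  regression estimate with multipliers {0.3, 0.7, 1, 1.4} (real data) or
  {0.01, 0.1, 0.3, 0.7, 1, 1.4} (simulation, the "low-h2" grid — small h²
  means strong shrinkage, which is what rescues the grid under
  misspecification). The default p grid is 21 values log-spaced in
  [10⁻⁵, 1].
- auto mode re-estimates both parameters each sweep: p ~ Beta(1+M_c,
  1+M−M_c) from the causal count and h² = βᵀRβ (always with the unshrunk R;
  the shrink is sampler regularization, not a model change). Defaults: 10
  chains with initial p log-spaced in [10⁻⁴, 0.2], 100 burn-in + 400 kept
  sweeps. A chain is flagged divergent when its h² trace exceeds 1.5 or p
  pins at 1 for more than 50 consecutive sweeps; divergent chains are
  dropped from the posterior mean, and an all-divergent result is flagged,
  not raised.
- Two robustness controls: `shrink_corr` multiplies the off-diagonal LD
  contribution to the residual (equivalent to running the plain sampler on
  cR + (1−c)I; presets 0.9 for simulation, 0.95 for real data), and
  `allow_jump_sign=False` zeroes a draw whose sign conflicts with the
  variant's current non-zero effect, forcing effects through 0 before
  changing sign (prevents oscillation under large misspecifications).

Degenerate input note: on exactly-null data h² collapses toward 0, the slab
variance vanishes, the inclusion Bayes factor tends to 1, and p becomes
unidentified (its trace wanders). h² and the posterior-mean effects remain
well-behaved; p estimates from auto mode are only meaningful when h² is
bounded away from 0.

**LD-score regression** (`ldsc_h2`) regresses χ² = Z² on x = ℓ·n/M with an
intercept, two-step weighted least squares (provisional slope b₀ seeds
weights 1/(2(1+b₀x)²ℓ), one reweighting pass), block-jackknife standard
errors (default 30 contiguous blocks). The slope is the h² estimate.

## LD reference

`build_ld` stores Pearson correlations only within a genetic-distance
window (default 3 cM — the windowed model assumes LD has died beyond it).
`split_blocks` finds the contiguous partition minimizing weight·C2 + C1
(C1 = squared correlation discarded outside blocks, C2 = Σ block sizes²) by
an exact dynamic program, with `max_r2` forbidding any outside-block squared
correlation above the threshold (boundaries spanned by such a pair are
disallowed; an unsatisfiable instance returns an infeasible result carrying
the binding pair). The printed default weight is 5, but C1 and C2 live on
different scales — C1 grows with panel size and LD, C2 with the square of
block sizes — so the weight and the admissible block-count range are
exposed as parameters and both cost components are always reported.
`apply_blocks` zeroes cross-block entries (reporting the kept fraction);
`shrink_offdiag(c)` returns cR + (1−c)I. The on-disk format (SFBM) stores
each column as (first-row index, run length, contiguous float64 values) —
about half the bytes of index/value pairs on run-dominated columns — plus a
trailing offset table for random column access and a JSON sidecar with the
variant grid.

## The synthetic-data generator

Genotypes are a mosaic of founder haplotypes: each haplotype copies
segments from a pool of K founders, switching to a random founder between
adjacent variants with probability 1 − exp(−ρ·ΔcM). This yields exact
{0,1,2} genotypes in Hardy–Weinberg proportions whose correlation between
two variants is exp(−ρ·d)·ρ_founder, i.e. distance-decaying LD whose
strength is set by the founder-pool size. The genetic map is either uniform
or a hotspot map (0.01 cM cold intervals; 3% of intervals add an
Exp(1.5 cM) jump), which makes LD blocky the way recombination hotspots do
in real chromosomes.

Study-condition defaults for the three misspecification scenarios (and the
benchmark): K = 8 founders, recombination rate 1.5/cM, hotspot map,
heritability 0.2 with 5% of variants causal. These were fixed by three
mechanistic requirements, not by tuning to outcomes: (1) LD must genuinely
vanish within the 3 cM window, otherwise the truncated correlation matrix
is severely non-positive-definite (λ_min ≈ −1.8 at rate 0.3/cM) and every
Gibbs-type solver explodes — with rate 1.5/cM the truncation error is
negligible and λ_min ≈ 0; (2) a small founder pool produces near-duplicate
variant pairs (r² ≈ 1), which real chromosome-22 data has in abundance and
which drive the misspecification pathologies of interest (e.g. the auto
sampler's polygenicity estimate escaping to 1 under a wrong per-variant n);
(3) hotspots give block boundaries natural, nearly-free locations —
with a uniform map, imposed blocks always cut real LD.

Dosages are true posterior means D = E[G | G+ε] under the HWE prior with
Gaussian channel noise, the per-variant noise sd calibrated by quadrature +
bisection so var(D) = INFO·2f(1−f). A posterior mean is bounded in [0,2]
and satisfies cov(D,G) = var(D) exactly; INFO = 1 returns the genotypes
unchanged. Multiple-imputation GWAS samples hard calls from P(G|G+ε) and
pools by Rubin's rules (mean of estimates; within + (1+1/m)·between
variance); under this construction γ̂_MI ≈ γ̂_dosage·INFO.

Phenotypes: causal variants drawn uniformly, effects i.i.d. N(0, h²/n_causal)
on the scaled-genotype scale; the noise is orthogonalized against the
genetic component and rescaled so the in-sample heritability equals the
target exactly (a flag disables rescaling). Per-variant GWAS subsamples are
drawn independently per variant, mimicking a meta-analysis in which
different cohorts cover different variants.

The ld-mismatch scenario drifts the founder pool: each founder allele is
resampled from Bernoulli(f) with probability d (default 0.02, which puts
the cross-panel allele-frequency correlation near 0.99); drift 0 makes the
two panels exchangeable draws from the same pool.

What the generator does **not** emulate: realistic demography or selection,
MAF-dependent architectures, imputation-server error structure (the
Gaussian channel is idealized), strand issues, genotyping batch effects.
Passing tests therefore show the methods behave correctly under the modeled
misspecifications, not that real-data performance numbers transfer.

## Benchmark desk scale

The benchmark harness runs each scenario at 4,000 variants with
20,000/2,000/5,000 train/validation/test individuals over 10 seeds — large
enough for the misspecification mechanisms to operate, small enough that a
full experiment takes minutes on one core. Within the harness the Gibbs
grid uses 50 burn-in + 100 kept sweeps per point with a 5-value p grid
({0.003, 0.01, 0.03, 0.1, 0.3}) and the auto runs use 5 chains with 100 +
250 sweeps; the library defaults stay at their full values. The
standard-grid and low-h2 selections share one sweep over the 6-multiplier
h² grid (the standard grid selects only among multipliers ≥ 0.3). Block
runs use 10–14 blocks (chromosome-22-like) with a split weight of 10⁻⁴:
with the block count already pinned, boundary placement should minimize
the discarded correlation, and at this panel size the printed weight of 5
would let the size-balance term drag boundaries onto weak hotspots.
Confidence intervals are non-parametric bootstraps (1,000 replicates) of
the per-seed mean.
Absolute r² values at this scale are not comparable to biobank-scale
results; only the directional contrasts (true vs max vs imputed n,
corrected vs uncorrected, matched vs mismatched LD, blocks vs none) are
meaningful, and those are what the test suite asserts.

## Known limitations

- The sampler's conditional-update formulas assume the windowed, blocked R
  is close to positive definite; heavily truncated LD (window shorter than
  the LD length scale) destabilizes any Gibbs/coordinate scheme.
- `ldsc_h2` is a minimal two-step WLS implementation for anchoring h²
  grids, not a replacement for a full LDSC analysis (no partitioned
  heritability, no sample-overlap correction).
- Binary-trait support is analytic (effective-n scale at ingestion); the
  simulator produces quantitative traits only.
- Allele matching reconciles exact and swapped allele pairs on (chr, pos)
  and drops palindromic variants by default; it does not attempt
  strand-flip rescue of ambiguous variants.
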