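"""Bayesian spike-and-slab PGS models (the LDpred2 family).

The model: scaled marginal effects beta_hat ~ N(R beta, R/n), with a
spike-and-slab prior beta_j ~ N(0, h2/(M p)) with probability p, else 0.
Variants:

- ``fit_inf``: the infinitesimal closed form (p = 1),
  beta = (R + M/(n h2) I)^-1 beta_hat, solved per LD block;
- ``gibbs_fit`` grid mode: Gibbs sampling at fixed (p, h2);
- ``gibbs_fit`` auto mode: p and h2 re-estimated each sweep from the sampled
  effects, with two robustness controls: ``shrink_corr`` multiplies the
  off-diagonal LD contribution to the residual (a regularization), and
  ``allow_jump_sign=False`` forces effects to pass through zero before
  changing sign across sweeps;
- ``build_h2_grid`` / ``grid_search``: the low-heritability grid anchored to
  the LD-score-regression estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._kernels import gibbs_sampler
from .ldref import LDMatrix

__all__ = [
    "GibbsConfig",
    "GibbsResult",
    "LDSCFit",
    "ldsc_h2",
    "fit_inf",
    "gibbs_fit",
    "build_h2_grid",
    "grid_search",
]

#: robustness presets for the auto sampler
AUTO_ROB_SIMULATION = dict(shrink_corr=0.9, allow_jump_sign=False)
AUTO_ROB_REAL = dict(shrink_corr=0.95, allow_jump_sign=False)

DEFAULT_P_GRID = np.logspace(-5, 0, 21)
H2_MULTIPLIERS = {
    "real": (0.3, 0.7, 1.0, 1.4),
    "simulation": (0.01, 0.1, 0.3, 0.7, 1.0, 1.4),
}


@dataclass
class LDSCFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    n_blocks: int

    @property
    def h2(self) -> float:
        return self.slope


def _wls(x, y, w):
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ y
    return np.linalg.solve(A, b)


def ldsc_h2(z: np.ndarray, ld_sc: np.ndarray, n, M: int | None = None,
            n_jackknife_blocks: int = 30) -> LDSCFit:
    """LD-score regression of chi2 = Z^2 on x = l * n / M.

    Two-step weighted least squares: a provisional slope seeds the weights
    1 / (2 (1 + b x)^2 l), one reweighted pass refines it.  Standard errors
    come from a contiguous block jackknife.  The slope is the heritability
    estimate on the scaled parameterization.
    """
    z = np.asarray(z, dtype=float)
    ld_sc = np.asarray(ld_sc, dtype=float)
    if np.any(ld_sc <= 0):
        raise ValueError("LD scores must be positive")
    if z.shape != ld_sc.shape:
        raise ValueError("inputs must align")
    m = z.shape[0]
    if M is None:
        M = m
    if M < 2:
        raise ValueError("need at least 2 variants")
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), (m,))
    chi2 = z**2
    x = ld_sc * n_arr / M

    def fit_once(idx):
        xi, ci, li = x[idx], chi2[idx], ld_sc[idx]
        b0 = max((ci.mean() - 1.0) / max(xi.mean(), 1e-12), 0.0)
        for _ in range(2):
            w = 1.0 / (2.0 * (1.0 + b0 * xi) ** 2 * li)
            a, b = _wls(xi, ci, w)
            b0 = max(b, 0.0)
        return a, b

    idx_all = np.arange(m)
    intercept, slope = fit_once(idx_all)

    nb = int(min(n_jackknife_blocks, m // 2)) or 1
    edges = np.linspace(0, m, nb + 1).astype(int)
    jk = np.empty((nb, 2))
    for b in range(nb):
        mask = np.ones(m, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        jk[b] = fit_once(idx_all[mask])
    se = np.sqrt((nb - 1) / nb * np.sum((jk - jk.mean(axis=0)) ** 2, axis=0))
    return LDSCFit(intercept=float(intercept), slope=float(slope),
                   intercept_se=float(se[0]), slope_se=float(se[1]),
                   n_blocks=nb)


def _block_slices(ld: LDMatrix):
    if ld.blocks is None:
        return [slice(0, ld.n_variants)]
    ids = np.asarray(ld.blocks)
    out = []
    start = 0
    for i in range(1, len(ids) + 1):
        if i == len(ids) or ids[i] != ids[i - 1]:
            out.append(slice(start, i))
            start = i
    return out


def fit_inf(beta_hat: np.ndarray, ld: LDMatrix, n, h2: float) -> np.ndarray:
    """Infinitesimal closed form: solve (R + diag(M/(n_j h2))) beta =
    beta_hat independently per LD block (whole panel = one block)."""
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    beta_hat = np.asarray(beta_hat, dtype=float)
    m = beta_hat.shape[0]
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), (m,))
    ridge = m / (n_arr * h2)
    out = np.empty(m)
    R = ld.matrix.tocsc()
    for sl in _block_slices(ld):
        sub = R[sl, sl]
        k = sub.shape[0]
        if k <= 800:
            A = sub.toarray()
            A[np.arange(k), np.arange(k)] += ridge[sl]
            out[sl] = np.linalg.solve(A, beta_hat[sl])
        else:
            A = (sub + sp.diags(ridge[sl])).tocsc()
            out[sl] = spla.spsolve(A, beta_hat[sl])
    return out


@dataclass
class GibbsConfig:
    """Sampler configuration.

    Grid mode uses fixed (p, h2); auto mode re-estimates them every sweep
    starting from ``p_init``/``h2_init``.  ``shrink_corr`` and
    ``allow_jump_sign`` are the robustness controls; the presets
    AUTO_ROB_SIMULATION (0.9) and AUTO_ROB_REAL (0.95) both disable sign
    jumps.
    """

    p: float = 0.1
    h2: float = 0.1
    shrink_corr: float = 1.0
    allow_jump_sign: bool = True
    burn_in: int = 100
    num_iter: int = 400
    n_chains: int = 10
    p_init_range: tuple[float, float] = (1e-4, 0.2)
    h2_guard: float = 1.5
    p_pin_limit: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        if self.h2 <= 0:
            raise ValueError("h2 must be positive")
        if not (0.0 <= self.shrink_corr <= 1.0):
            raise ValueError("shrink_corr must lie in [0, 1]")


@dataclass
class GibbsResult:
    beta: np.ndarray  # posterior mean of scaled effects
    p_est: float | None
    h2_est: float | None
    p_traces: list
    h2_traces: list
    diverged: np.ndarray  # per chain
    mode: str
    beta0_traces: list = field(default_factory=list)  # per-sweep beta[0]

    @property
    def all_diverged(self) -> bool:
        return bool(self.diverged.all())


def gibbs_fit(beta_hat: np.ndarray, ld: LDMatrix, n,
              config: GibbsConfig | None = None, mode: str = "grid") -> GibbsResult:
    """Run the spike-and-slab Gibbs sampler.

    Grid mode: one chain at fixed (p, h2).  Auto mode: ``n_chains`` chains
    with initial p log-spaced over ``p_init_range``; each sweep re-draws
    p ~ Beta(1 + Mc, 1 + M - Mc) and sets h2 = beta' R beta (unshrunk R).
    Divergent chains (h2 above the guard, or p pinned at 1 for more than
    ``p_pin_limit`` consecutive sweeps) are dropped from the posterior mean;
    if every chain diverges the result is flagged, not raised.
    """
    if mode not in ("grid", "auto"):
        raise ValueError("mode must be 'grid' or 'auto'")
    config = config or GibbsConfig()
    beta_hat = np.asarray(beta_hat, dtype=float)
    if np.any(~np.isfinite(beta_hat)):
        raise ValueError("NaN/inf in scaled effects")
    m = beta_hat.shape[0]
    if ld.n_variants != m:
        raise ValueError("LD matrix and effects are not aligned")
    n_arr = np.ascontiguousarray(
        np.broadcast_to(np.asarray(n, dtype=float), (m,)))
    indptr, indices, data = ld.csc_arrays()

    if mode == "grid":
        inits = [(config.p, config.h2)]
    else:
        lo, hi = config.p_init_range
        p_inits = np.logspace(np.log10(lo), np.log10(hi),
                              max(config.n_chains, 1))
        inits = [(float(p0), config.h2) for p0 in p_inits]

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(inits))
    betas, p_traces, h2_traces, b0_traces, diverged = [], [], [], [], []
    for (p0, h20), s in zip(inits, seeds):
        bm, pt, ht, b0, div = gibbs_sampler(
            indptr, indices, data, beta_hat, n_arr, float(p0), float(h20),
            float(config.shrink_corr), config.allow_jump_sign,
            mode == "auto", int(config.burn_in), int(config.num_iter),
            float(config.h2_guard), int(config.p_pin_limit), int(s))
        if np.any(~np.isfinite(bm)):
            div = True
        betas.append(bm)
        p_traces.append(pt)
        h2_traces.append(ht)
        b0_traces.append(b0)
        diverged.append(div)
    diverged = np.asarray(diverged, dtype=bool)
    keep = ~diverged
    if keep.any():
        beta = np.mean([b for b, k in zip(betas, keep) if k], axis=0)
    else:
        beta = np.zeros(m)
    p_est = h2_est = None
    if mode == "auto" and keep.any():
        kept = slice(config.burn_in, None)
        p_est = float(np.mean([t[kept].mean()
                               for t, k in zip(p_traces, keep) if k]))
        h2_est = float(np.mean([t[kept].mean()
                                for t, k in zip(h2_traces, keep) if k]))
    return GibbsResult(beta=beta, p_est=p_est, h2_est=h2_est,
                       p_traces=p_traces, h2_traces=h2_traces,
                       diverged=diverged, mode=mode, beta0_traces=b0_traces)


def build_h2_grid(h2_ldsc: float, mode: str = "real") -> np.ndarray:
    """Heritability grid anchored to the LDSC estimate: multipliers
    {0.3, 0.7, 1, 1.4} for real data, extended down to {0.01, 0.1, ...} for
    large misspecifications (the low-h2 grid)."""
    if h2_ldsc <= 0:
        raise ValueError("h2_ldsc must be positive")
    try:
        mult = H2_MULTIPLIERS[mode]
    except KeyError:
        raise ValueError("mode must be 'real' or 'simulation'") from None
    return np.asarray(mult, dtype=float) * h2_ldsc


def grid_search(beta_hat: np.ndarray, ld: LDMatrix, n,
                p_grid=None, h2_grid=None, scorer=None,
                config: GibbsConfig | None = None):
    """Run grid-mode Gibbs over the Cartesian (p, h2) grid, score each fit
    on validation data, and return the argmax.

    ``scorer`` maps a scaled-effect vector to a scalar.  Ties break toward
    more regularization (smaller h2, then smaller p).  Returns
    (best_p, best_h2, best_beta, table) where table lists every grid point.
    """
    if scorer is None:
        raise ValueError("a validation scorer is required")
    p_grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, float)
    h2_grid = np.asarray(h2_grid, dtype=float)
    if p_grid.size == 0 or h2_grid.size == 0:
        raise ValueError("grids must be non-empty")
    base = config or GibbsConfig()
    results = []
    for h2 in np.sort(h2_grid):
        for p in np.sort(p_grid):
            cfg = replace(base, p=float(p), h2=float(h2))
            res = gibbs_fit(beta_hat, ld, n, cfg, mode="grid")
            score = -np.inf if res.all_diverged else float(scorer(res.beta))
            results.append((float(p), float(h2), score, res))
    usable = [r for r in results if np.isfinite(r[2])]
    if not usable:
        raise ValueError("all grid fits diverged")
    best = None
    for p, h2, score, res in results:
        if not np.isfinite(score):
            continue
        if best is None or score > best[2]:
            best = (p, h2, score, res)
        elif score == best[2] and (h2, p) < (best[1], best[0]):
            best = (p, h2, score, res)
    table = [(p, h2, s) for p, h2, s, _ in results]
    return best[0], best[1], best[3].beta, table
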