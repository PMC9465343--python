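"""Elastic-net PGS solver on summary statistics (lassosum2).

Solves, per (lambda, delta) on a grid, the penalized regression implied by
scaled marginal effects beta_hat and an LD matrix R:

    beta_j <- soft_threshold(u_j, lambda_j) / (1 + delta_j),
    u_j = beta_hat_j - (R beta)_j + beta_j,

by cyclic coordinate descent with the rotated residual R beta cached and
updated incrementally (only stored neighbors of a changed coordinate are
touched).  Per-variant penalty factors q_j = max_k(n_k)/n_j multiply both
lambda and delta, penalizing variants with smaller GWAS sample sizes more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import cd_elastic_net
from .ldref import LDMatrix

__all__ = ["LassosumGrid", "LassosumPath", "fit_lassosum2", "pick_best"]

DEFAULT_DELTAS = (0.001, 0.01, 0.1, 1.0)


@dataclass
class LassosumGrid:
    """Hyper-parameter grid.  lambdas default to 30 values log-spaced between
    lambda0 = max_j |beta_hat_j| (the smallest lambda with an all-zero
    solution) and lambda0/100, in decreasing order for warm starts."""

    lambdas: np.ndarray | None = None
    deltas: tuple = DEFAULT_DELTAS
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    tol_ratio: float = 1e-5  # convergence: max |delta beta| < tol_ratio * lambda0
    max_iter: int = 500
    divergence_guard: float = 5.0

    def resolve_lambdas(self, beta_hat: np.ndarray) -> np.ndarray:
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
        else:
            lam0 = float(np.max(np.abs(beta_hat)))
            if lam0 <= 0:
                lam0 = 1.0
            lam = np.logspace(np.log10(lam0),
                              np.log10(lam0 * self.lambda_min_ratio),
                              self.n_lambda)
        if np.any(np.diff(lam) > 0):
            lam = np.sort(lam)[::-1].copy()
        return lam


@dataclass
class LassosumPath:
    """Fitted scaled-effect vectors over the (lambda, delta) grid."""

    betas: np.ndarray  # (n_lambda, n_delta, m)
    lambdas: np.ndarray
    deltas: np.ndarray
    penalty_factors: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    diverged: np.ndarray

    def grid_points(self):
        for i, lam in enumerate(self.lambdas):
            for k, d in enumerate(self.deltas):
                yield (i, k), (lam, d)


def fit_lassosum2(beta_hat: np.ndarray, ld: LDMatrix,
                  n=None, grid: LassosumGrid | None = None) -> LassosumPath:
    """Fit the whole (lambda, delta) grid with warm starts along decreasing
    lambda within each delta.  Divergent fits (max |beta| beyond the guard)
    are flagged, not raised."""
    beta_hat = np.asarray(beta_hat, dtype=np.float64)
    if np.any(~np.isfinite(beta_hat)):
        raise ValueError("NaN/inf in scaled effects")
    m = beta_hat.shape[0]
    if ld.n_variants != m:
        raise ValueError("LD matrix and effects are not aligned")
    grid = grid or LassosumGrid()
    lambdas = grid.resolve_lambdas(beta_hat)
    deltas = np.asarray(grid.deltas, dtype=float)
    if np.any(deltas <= 0):
        raise ValueError("delta must be positive")
    if n is None:
        q = np.ones(m)
    else:
        n_arr = np.broadcast_to(np.asarray(n, dtype=float), (m,))
        if np.any(n_arr <= 0) or np.any(~np.isfinite(n_arr)):
            raise ValueError("sample sizes must be positive and finite")
        q = np.max(n_arr) / n_arr
    indptr, indices, data = ld.csc_arrays()
    lam0 = float(np.max(np.abs(beta_hat))) if m else 1.0
    tol = grid.tol_ratio * (lam0 if lam0 > 0 else 1.0)

    betas = np.zeros((len(lambdas), len(deltas), m))
    iters = np.zeros((len(lambdas), len(deltas)), dtype=np.int64)
    converged = np.zeros_like(iters, dtype=bool)
    diverged = np.zeros_like(iters, dtype=bool)
    for k, delta in enumerate(deltas):
        beta = np.zeros(m)
        v = np.zeros(m)
        for i, lam in enumerate(lambdas):
            it, conv, div = cd_elastic_net(
                indptr, indices, data, beta_hat, q, float(lam), float(delta),
                beta, v, tol, grid.max_iter, grid.divergence_guard)
            iters[i, k] = it
            converged[i, k] = conv
            diverged[i, k] = div
            betas[i, k] = beta
            if div:  # restart cold for the next lambda
                beta = np.zeros(m)
                v = np.zeros(m)
    return LassosumPath(betas=betas, lambdas=lambdas, deltas=deltas,
                        penalty_factors=q, iterations=iters,
                        converged=converged, diverged=diverged)


def pick_best(path: LassosumPath, scores: np.ndarray):
    """Return (lambda, delta, beta) maximizing the validation score.

    ``scores`` is (n_lambda, n_delta), NaN for unusable fits.  Ties break
    toward more regularization: larger lambda, then larger delta.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(path.lambdas), len(path.deltas)):
        raise ValueError("scores must align with the grid")
    usable = np.isfinite(scores) & ~path.diverged
    if not usable.any():
        raise ValueError("all fits diverged or unscored")
    best = -np.inf
    pick = None
    for i in range(scores.shape[0]):
        for k in range(scores.shape[1]):
            if not usable[i, k]:
                continue
            s = scores[i, k]
            if s > best:
                best, pick = s, (i, k)
            elif s == best and pick is not None:
                bi, bk = pick
                # larger lambda wins; lambdas are stored decreasing
                if i < bi or (i == bi and path.deltas[k] > path.deltas[bk]):
                    pick = (i, k)
    i, k = pick
    return float(path.lambdas[i]), float(path.deltas[k]), path.betas[i, k]
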