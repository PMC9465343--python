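"""Independent oracles used by the test suite.

Everything here is deliberately written against the mathematical definition
of each problem (dense linear algebra, exhaustive enumeration, generic
first-order optimization, closed-form posteriors) and never calls the
implementation paths it is used to check.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal, norm


def soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def prox_grad_elastic_net(R, beta_hat, lam, delta, q=None, n_iter=200_000,
                          tol=1e-12):
    """Proximal-gradient minimizer of
    1/2 b'Rb - beta_hat'b + 1/2 sum_j delta_j b_j^2 + sum_j lam_j |b_j|,
    with per-variant penalties lam_j = lam*q_j, delta_j = delta*q_j."""
    m = len(beta_hat)
    q = np.ones(m) if q is None else np.asarray(q, dtype=float)
    lam_j = lam * q
    delta_j = delta * q
    L = np.linalg.eigvalsh(R).max() + delta_j.max()
    t = 1.0 / L
    b = np.zeros(m)
    for _ in range(n_iter):
        grad = R @ b - beta_hat + delta_j * b
        b_new = soft_threshold(b - t * grad, t * lam_j)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    return b


def enumerate_partitions(m, max_block_size, n_blocks_range=None):
    """All contiguous partitions of range(m) as boundary tuples."""
    for mask in itertools.product([0, 1], repeat=m - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [m]
        sizes = np.diff(bounds)
        if np.any(sizes > max_block_size):
            continue
        if n_blocks_range is not None and len(sizes) not in n_blocks_range:
            continue
        yield np.asarray(bounds)


def partition_cost(R_dense, bounds, weight):
    """weight * sum(sizes^2) + sum of squared correlations outside blocks
    (unordered pairs, off-diagonal)."""
    m = R_dense.shape[0]
    ids = np.empty(m, dtype=int)
    for b in range(len(bounds) - 1):
        ids[bounds[b]:bounds[b + 1]] = b
    iu = np.triu_indices(m, 1)
    outside = ids[iu[0]] != ids[iu[1]]
    C1 = float(np.sum(R_dense[iu][outside] ** 2))
    C2 = float(np.sum(np.diff(bounds).astype(float) ** 2))
    return weight * C2 + C1, C1, C2


def partition_feasible(R_dense, bounds, max_r2):
    m = R_dense.shape[0]
    ids = np.empty(m, dtype=int)
    for b in range(len(bounds) - 1):
        ids[bounds[b]:bounds[b + 1]] = b
    iu = np.triu_indices(m, 1)
    outside = ids[iu[0]] != ids[iu[1]]
    return not np.any(R_dense[iu][outside] ** 2 > max_r2)


def brute_force_split(R_dense, max_block_size, max_r2, weight,
                      n_blocks_range=None):
    """Optimal contiguous partition by exhaustive enumeration (M <= 12)."""
    best = None
    for bounds in enumerate_partitions(R_dense.shape[0], max_block_size,
                                       n_blocks_range):
        if not partition_feasible(R_dense, bounds, max_r2):
            continue
        cost, C1, C2 = partition_cost(R_dense, bounds, weight)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, bounds, C1, C2)
    return best  # None when infeasible


def spike_slab_marginal_cdf(xs, beta_hat, R, n, p, sigma2):
    """Exact posterior CDF of beta_1 for the 2-variant spike-and-slab model:
    beta_hat ~ N(R beta, R/n), beta_j ~ p N(0, sigma2) + (1-p) delta_0.

    Enumerates the four inclusion patterns; each pattern's weight is the
    prior times the Gaussian marginal likelihood, and beta_1 | pattern is
    either the atom at 0 or a Gaussian with precision n R_AA + I/sigma2.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    R = np.asarray(R, dtype=float)
    like_cov = R / n
    weights = {}
    comps = {}
    for pattern in itertools.product([0, 1], repeat=2):
        A = [j for j, a in enumerate(pattern) if a]
        prior_w = np.prod([p if a else 1 - p for a in pattern])
        if A:
            RA = R[:, A]
            cov = like_cov + sigma2 * (RA @ RA.T)
        else:
            cov = like_cov
        ml = multivariate_normal(mean=np.zeros(2), cov=cov).pdf(beta_hat)
        weights[pattern] = prior_w * ml
        if 0 in A:
            prec = n * R[np.ix_(A, A)] + np.eye(len(A)) / sigma2
            cov_post = np.linalg.inv(prec)
            mean_post = cov_post @ (n * beta_hat[A])
            k = A.index(0)
            comps[pattern] = (mean_post[k], np.sqrt(cov_post[k, k]))
        else:
            comps[pattern] = None
    total = sum(weights.values())
    cdf = np.zeros_like(np.asarray(xs, dtype=float))
    for pattern, w in weights.items():
        w = w / total
        if comps[pattern] is None:
            cdf += w * (np.asarray(xs) >= 0.0)
        else:
            mu, sd = comps[pattern]
            cdf += w * norm.cdf(xs, mu, sd)
    return cdf


def ols_slope_se(x, y):
    """Textbook simple-regression slope and standard error (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    slope = (xc @ yc) / (xc @ xc)
    resid = yc - slope * xc
    sigma2 = (resid @ resid) / (n - 2)
    return slope, np.sqrt(sigma2 / (xc @ xc))
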