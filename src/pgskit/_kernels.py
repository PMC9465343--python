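"""Numba kernels for the hot loops.

Everything here is deterministic given the integer seed passed in; numba's
np.random state is per-thread, and all callers run these kernels
single-threaded.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mosaic_haplotypes(n_individuals, pos_cm, founder_alleles, recomb_rate,
                      seed):
    """Copy founder segments into haplotype pairs with recombination
    breakpoints.

    Each haplotype starts on a uniformly chosen founder and switches to a
    fresh uniform founder between adjacent variants with probability
    1 - exp(-rate * d_cM).  Returns (G, idx): the genotype matrix
    (n_individuals x m, int8) and the founder index matrix per haplotype
    (2*n_individuals x m, int8) used for per-column resampling.
    """
    np.random.seed(seed)
    K, m = founder_alleles.shape
    G = np.empty((n_individuals, m), dtype=np.int8)
    idx = np.empty((2 * n_individuals, m), dtype=np.int8)
    # precompute per-interval switch probabilities
    p_switch = np.empty(m, dtype=np.float64)
    p_switch[0] = 1.0
    for j in range(1, m):
        d = pos_cm[j] - pos_cm[j - 1]
        if recomb_rate == np.inf:
            p_switch[j] = 1.0
        else:
            p_switch[j] = 1.0 - np.exp(-recomb_rate * d)
    for i in range(n_individuals):
        c1 = np.random.randint(0, K)
        c2 = np.random.randint(0, K)
        idx[2 * i, 0] = c1
        idx[2 * i + 1, 0] = c2
        G[i, 0] = founder_alleles[c1, 0] + founder_alleles[c2, 0]
        for j in range(1, m):
            if np.random.random() < p_switch[j]:
                c1 = np.random.randint(0, K)
            if np.random.random() < p_switch[j]:
                c2 = np.random.randint(0, K)
            idx[2 * i, j] = c1
            idx[2 * i + 1, j] = c2
            G[i, j] = founder_alleles[c1, j] + founder_alleles[c2, j]
    return G, idx


@njit(cache=True)
def gwas_per_variant(X, y, counts, seed):
    """Simple linear regression of y on each column, on an independent
    per-variant subsample of the given size.

    Returns (beta, se, freq, used_n, bad) where bad marks zero-variance
    columns within their subsample.  X may be int8 genotypes or float32/64
    dosages.
    """
    np.random.seed(seed)
    n, m = X.shape
    beta = np.empty(m)
    se = np.empty(m)
    freq = np.empty(m)
    used_n = np.empty(m, dtype=np.int64)
    bad = np.zeros(m, dtype=np.bool_)
    perm = np.empty(n, dtype=np.int64)
    for j in range(m):
        k = counts[j]
        used_n[j] = k
        if k == n:
            sx = 0.0
            sy = 0.0
            sxx = 0.0
            sxy = 0.0
            syy = 0.0
            for i in range(n):
                g = np.float64(X[i, j])
                sx += g
                sy += y[i]
                sxx += g * g
                sxy += g * y[i]
                syy += y[i] * y[i]
        else:
            for i in range(n):
                perm[i] = i
            # partial Fisher-Yates: first k entries are the subsample
            for i in range(k):
                r = i + np.random.randint(0, n - i)
                tmp = perm[i]
                perm[i] = perm[r]
                perm[r] = tmp
            sx = 0.0
            sy = 0.0
            sxx = 0.0
            sxy = 0.0
            syy = 0.0
            for t in range(k):
                i = perm[t]
                g = np.float64(X[i, j])
                sx += g
                sy += y[i]
                sxx += g * g
                sxy += g * y[i]
                syy += y[i] * y[i]
        kf = np.float64(k)
        ssx = sxx - sx * sx / kf
        ssy = syy - sy * sy / kf
        sxy_c = sxy - sx * sy / kf
        freq[j] = sx / (2.0 * kf)
        if ssx <= 0.0 or k < 3:
            beta[j] = np.nan
            se[j] = np.nan
            bad[j] = True
            continue
        b = sxy_c / ssx
        rss = ssy - b * sxy_c
        if rss < 0.0:
            rss = 0.0
        sigma2 = rss / (kf - 2.0)
        beta[j] = b
        se[j] = np.sqrt(sigma2 / ssx)
    return beta, se, freq, used_n, bad


@njit(cache=True)
def cd_elastic_net(indptr, indices, data, beta_hat, q, lam, delta, beta, v,
                   tol, max_iter, guard):
    """One elastic-net coordinate-descent fit at a single (lambda, delta).

    beta and v (= R @ beta) are updated in place, enabling warm starts along
    the lambda path.  Per-variant penalties are lam*q[j], delta*q[j].
    Returns (n_sweeps, converged, diverged).
    """
    m = beta_hat.shape[0]
    for it in range(max_iter):
        max_delta = 0.0
        max_abs = 0.0
        for j in range(m):
            bj = beta[j]
            u = beta_hat[j] - (v[j] - bj)
            lj = lam * q[j]
            dj = delta * q[j]
            au = abs(u)
            if au > lj:
                new = np.sign(u) * (au - lj) / (1.0 + dj)
            else:
                new = 0.0
            diff = new - bj
            if diff != 0.0:
                beta[j] = new
                for p in range(indptr[j], indptr[j + 1]):
                    v[indices[p]] += diff * data[p]
                ad = abs(diff)
                if ad > max_delta:
                    max_delta = ad
            anew = abs(new)
            if anew > max_abs:
                max_abs = anew
        if max_abs > guard:
            return it + 1, False, True
        if max_delta < tol:
            return it + 1, True, False
    return max_iter, False, False


@njit(cache=True)
def gibbs_sampler(indptr, indices, data, beta_hat, n_vec, p_init, h2_init,
                  shrink_corr, allow_jump_sign, auto, burn_in, num_iter,
                  h2_guard, p_pin_limit, seed):
    """Spike-and-slab Gibbs sampler over scaled effects.

    data holds the *unshrunk* correlation entries; shrink_corr multiplies the
    off-diagonal part of the residual only, so the h2 update beta' R beta uses
    the unshrunk R.  In auto mode p and h2 are re-estimated each sweep
    (p ~ Beta(1+Mc, 1+M-Mc), h2 = beta' R beta); in grid mode they stay fixed.

    Returns (post_mean, p_trace, h2_trace, beta0_trace, diverged), where
    beta0_trace records the first coordinate's sampled value every sweep
    (used for stationarity diagnostics).
    """
    np.random.seed(seed)
    m = beta_hat.shape[0]
    M = np.float64(m)
    beta = np.zeros(m)
    v = np.zeros(m)  # R @ beta, unshrunk R
    post_sum = np.zeros(m)
    total = burn_in + num_iter
    p_trace = np.empty(total)
    h2_trace = np.empty(total)
    beta0_trace = np.empty(total)
    p = p_init
    h2 = h2_init
    diverged = False
    pinned = 0
    kept = 0
    for it in range(total):
        sigma2 = h2 / (M * p)
        if sigma2 <= 0.0:
            sigma2 = 1e-12
        mc = 0
        for j in range(m):
            bj = beta[j]
            u = beta_hat[j] - shrink_corr * (v[j] - bj)
            nj = n_vec[j]
            ns2 = nj * sigma2
            shrink = ns2 / (1.0 + ns2)
            # log odds of inclusion
            arg = 0.5 * u * u * nj * shrink
            if arg > 700.0:
                arg = 700.0
            odds = ((1.0 - p) / p) * np.sqrt(1.0 + ns2) * np.exp(-arg)
            post_p = 1.0 / (1.0 + odds)
            new = 0.0
            if np.random.random() < post_p:
                mean = u * shrink
                sd = np.sqrt(sigma2 / (1.0 + ns2))
                new = mean + sd * np.random.normal()
                if (not allow_jump_sign) and bj != 0.0 and new * bj < 0.0:
                    new = 0.0
            diff = new - bj
            if diff != 0.0:
                beta[j] = new
                for t in range(indptr[j], indptr[j + 1]):
                    v[indices[t]] += diff * data[t]
            if new != 0.0:
                mc += 1
        if auto:
            p = np.random.beta(1.0 + mc, 1.0 + M - mc)
            if p < 1e-5:
                p = 1e-5
            h2 = 0.0
            for j in range(m):
                h2 += beta[j] * v[j]
            if h2 < 1e-4:
                h2 = 1e-4
        p_trace[it] = p
        h2_trace[it] = h2
        beta0_trace[it] = beta[0]
        if auto:
            if h2 > h2_guard:
                diverged = True
            if p > 1.0 - 1.0 / M:
                pinned += 1
                if pinned > p_pin_limit:
                    diverged = True
            else:
                pinned = 0
        if it >= burn_in:
            kept += 1
            for j in range(m):
                post_sum[j] += beta[j]
    post_mean = post_sum / max(kept, 1)
    return post_mean, p_trace, h2_trace, beta0_trace, diverged


@njit(cache=True)
def posterior_mean_dosage(S, G, sigma, f, exact, out):
    """D = E[G | s] under HWE(f) per variant, s the noisy channel output;
    exact columns (INFO = 1) copy the genotype.  Writes into out."""
    n, m = G.shape
    for j in range(m):
        fj = f[j]
        p0 = (1.0 - fj) * (1.0 - fj)
        p1 = 2.0 * fj * (1.0 - fj)
        p2 = fj * fj
        if exact[j]:
            for i in range(n):
                out[i, j] = G[i, j]
            continue
        sj = sigma[j]
        inv2 = 1.0 / (2.0 * sj * sj)
        for i in range(n):
            s = S[i, j]
            w0 = p0 * np.exp(-s * s * inv2)
            d1 = s - 1.0
            w1 = p1 * np.exp(-d1 * d1 * inv2)
            d2 = s - 2.0
            w2 = p2 * np.exp(-d2 * d2 * inv2)
            tot = w0 + w1 + w2
            if tot <= 0.0:
                # far tail: collapse to the nearest genotype
                out[i, j] = min(max(round(s), 0.0), 2.0)
            else:
                out[i, j] = (w1 + 2.0 * w2) / tot
    return out


@njit(cache=True)
def split_dp_free(S, allowed, max_block_size, weight, m):
    """Partition DP without a block-count constraint.

    f[j] = min cost of partitioning [0, j); cost of a block [i, j) is
    weight*(j-i)^2 minus the squared correlations it keeps inside.
    Returns (f, prev).
    """
    INF = np.inf
    f = np.full(m + 1, INF)
    prev = np.full(m + 1, -1, dtype=np.int64)
    f[0] = 0.0
    for j in range(1, m + 1):
        if (not allowed[j]) and j != m:
            continue
        i0 = j - max_block_size
        if i0 < 0:
            i0 = 0
        for i in range(i0, j):
            if f[i] == INF or ((not allowed[i]) and i != 0):
                continue
            cost = f[i] + weight * (j - i) ** 2 - S[i, j - i - 1]
            if cost < f[j]:
                f[j] = cost
                prev[j] = i
    return f, prev


@njit(cache=True)
def split_dp_counted(S, allowed, max_block_size, weight, m, kmax):
    """Partition DP with an explicit block-count dimension."""
    INF = np.inf
    f = np.full((kmax + 1, m + 1), INF)
    prev = np.full((kmax + 1, m + 1), -1, dtype=np.int64)
    f[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for j in range(1, m + 1):
            if (not allowed[j]) and j != m:
                continue
            i0 = j - max_block_size
            if i0 < 0:
                i0 = 0
            for i in range(i0, j):
                if f[k - 1, i] == INF:
                    continue
                cost = f[k - 1, i] + weight * (j - i) ** 2 - S[i, j - i - 1]
                if cost < f[k, j]:
                    f[k, j] = cost
                    prev[k, j] = i
    return f, prev


@njit(cache=True)
def block_inside_sums(indptr, indices, data, max_block_size):
    """S[i, L-1] = sum of squared off-diagonal entries (unordered pairs) of the
    submatrix spanning variants [i, i+L), for L up to max_block_size.

    Built column by column: adding column j to a block starting at i
    contributes the squared entries r(a, j)^2 with i <= a < j.
    """
    m = indptr.shape[0] - 1
    S = np.zeros((m, max_block_size))
    for i in range(m):
        top = min(m, i + max_block_size)
        acc = 0.0
        S[i, 0] = 0.0
        for j in range(i + 1, top):
            for t in range(indptr[j], indptr[j + 1]):
                a = indices[t]
                if i <= a < j:
                    acc += data[t] * data[t]
            S[i, j - i] = acc
    return S
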