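"""Independent oracles used by the test suite.

These re-derive expected values by brute force or from first principles and
deliberately avoid the library code paths they are used to check.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import gammaln


def bh_stepup(pvals):
    """Hand-rolled Benjamini-Hochberg step-up, for checking bh_adjust."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact summation of hypergeometric pmf terms."""
    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total


def nb_lrt_stats(ya: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise NB LRT statistics, written independently of the package.

    Same model definition (pooled method-of-moments dispersion, common-mean
    null vs two-mean alternative) so it can drive a permutation null for the
    statistic.
    """
    na, nb = ya.shape[1], yb.shape[1]
    ma, mb = ya.mean(1), yb.mean(1)
    grand = (ya.sum(1) + yb.sum(1)) / (na + nb)
    ssw = ((ya - ma[:, None]) ** 2).sum(1) + ((yb - mb[:, None]) ** 2).sum(1)
    s2 = ssw / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(grand > 0, (s2 - grand) / np.maximum(grand, 1e-300) ** 2, 0.0)
    alpha = np.maximum(alpha, 1e-8)

    def ll(y, mu):
        mu = mu[:, None]
        r = (1.0 / alpha)[:, None]
        ok = mu > 0
        mus = np.where(ok, mu, 1.0)
        terms = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mus))
            + y * np.log(mus / (r + mus))
        )
        return np.where(ok, terms, 0.0).sum(1)

    return np.clip(
        2 * (ll(ya, ma) + ll(yb, mb) - ll(np.hstack([ya, yb]), grand)), 0, None
    )


def permutation_pvalues(
    ya: np.ndarray, yb: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Permutation p-values for the NB LRT statistic (add-one estimator)."""
    na = ya.shape[1]
    obs = nb_lrt_stats(ya, yb)
    pooled = np.hstack([ya, yb])
    n = pooled.shape[1]
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(ya.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stats = nb_lrt_stats(pooled[:, perm[:na]], pooled[:, perm[na:]])
        count_ge += stats >= obs - 1e-12
    return (1.0 + count_ge) / (n_perm + 1.0)
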