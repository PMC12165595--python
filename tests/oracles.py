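"""Independent brute-force oracles used to pin expected values in tests.

Everything here deliberately re-derives results by the most transparent
route available (exhaustive sorting, exact tail sums with integer
binomial coefficients, closed-form algebra) and never calls the code
paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

from airwayspec.io import ESOPHAGUS, TRACHEA


def brute_knn(points, labels, metas, query_idx, k, p, self_vote=True):
    """Exhaustive-sort K-NN for a query inside the training set.

    Returns (label, confidence_percent). Ordering: distance, then
    lexicographic (pair_id, organ, acq_index). Mirrors the documented
    contract using plain python sorting over all pairwise distances.
    """
    q = points[query_idx]
    cands = []
    for i, (pt, lab, m) in enumerate(zip(points, labels, metas)):
        if i == query_idx:
            continue
        d = (abs(pt[0] - q[0]) ** p + abs(pt[1] - q[1]) ** p) ** (1.0 / p)
        cands.append((d, m.pair_id, m.organ, m.acq_index, lab))
    cands.sort()
    votes = [c[4] for c in cands[:k]]
    if self_vote:
        votes.append(labels[query_idx])
    n_tra = votes.count(TRACHEA)
    n_eso = len(votes) - n_tra
    if n_tra > n_eso:
        return TRACHEA, 100.0 * n_tra / len(votes)
    if n_eso > n_tra:
        return ESOPHAGUS, 100.0 * n_eso / len(votes)
    return cands[0][4], 100.0 * (len(votes) // 2) / len(votes)


def binomial_tail_ge(x: int, n: int, prob: float) -> float:
    """P(X >= x) for X ~ Binomial(n, prob), exact integer-coefficient sum."""
    return sum(
        math.comb(n, j) * prob**j * (1.0 - prob) ** (n - j) for j in range(x, n + 1)
    )


def clopper_pearson_lower_bisect(x: int, n: int, alpha: float = 0.05,
                                 iters: int = 60) -> float:
    """Lower CP bound by bisecting P(X >= x | p) = alpha/2 on p in [0, 1]."""
    if x == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if binomial_tail_ge(x, n, mid) < alpha / 2.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def invert_features(cfg, r543: float, r578: float) -> tuple[float, float]:
    """Closed-form inversion of the generator's feature map.

    Solves the 2x2 linear system expressing the noiseless normalized
    trough reflectances in terms of the trough depths (d543, d578).
    """
    span = cfg.grid_stop - cfg.grid_start
    (c1, c2), (s1, s2) = cfg.trough_centers, cfg.trough_widths

    def B(lam):
        return 1.0 + cfg.baseline_slope * (lam - 561.0) / span

    def g(lam, c, s):
        return math.exp(-0.5 * ((lam - c) / s) ** 2)

    # r * B(561) * (1 - d1 g1(561) - d2 g2(561)) = B(lam) * (1 - d1 g1(lam) - d2 g2(lam))
    rows, rhs = [], []
    for lam, r in ((c1, r543), (c2, r578)):
        a1 = B(lam) * g(lam, c1, s1) - r * B(561.0) * g(561.0, c1, s1)
        a2 = B(lam) * g(lam, c2, s2) - r * B(561.0) * g(561.0, c2, s2)
        rows.append([a1, a2])
        rhs.append(B(lam) - r * B(561.0))
    d = np.linalg.solve(np.array(rows), np.array(rhs))
    return float(d[0]), float(d[1])
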