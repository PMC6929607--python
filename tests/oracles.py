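"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they are used to check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact integer enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, written the slow direct way."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def gaussian_mi(rho: float) -> float:
    """Closed-form mutual information (nats) of a bivariate Gaussian."""
    return -0.5 * math.log(1.0 - rho**2)


def pairwise_auc(scores, y) -> float:
    """AUC by direct enumeration of all (case, control) pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return float(wins / (len(pos) * len(neg)))


def ds_direct(x, y, epsilon: float = 1e-12) -> float:
    """Discriminating score by direct arithmetic (no shared helpers)."""
    x = list(map(float, x))
    y = list(map(float, y))
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    sdx = math.sqrt(sum((v - mx) ** 2 for v in x) / (len(x) - 1))
    sdy = math.sqrt(sum((v - my) ** 2 for v in y) / (len(y) - 1))
    return abs(mx - my) / (sdx + sdy + epsilon)
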