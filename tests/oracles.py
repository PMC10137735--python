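"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected value from first principles
(enumeration, textbook definitions, closed forms) without touching the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(p_values) -> list[float]:
    """Textbook Benjamini–Hochberg step-up adjusted values.

    Sort ascending, compute m·p_(i)/i, enforce monotonicity from the
    largest rank down, clip at 1, return in the input order.
    """
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adjusted[idx] = min(1.0, running)
    return adjusted


def pearson_closed_form(x, y) -> tuple[float, float]:
    """Sample correlation from raw sums, p from the t reference via the
    regularised incomplete beta function."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    # two-sided p = I_{df/(df+t²)}(df/2, 1/2)
    from scipy.special import betainc
    p = betainc(df / 2.0, 0.5, df / (df + t2))
    return r, float(p)


def hypergeom_upper_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def binary_distance_enum(x, y, tau: float = 0.0) -> float:
    """Asymmetric binary distance by position-by-position counting."""
    a = b = c = 0
    for xi, yi in zip(x, y):
        px, py = xi > tau, yi > tau
        if px and py:
            a += 1
        elif px:
            b += 1
        elif py:
            c += 1
    return 0.0 if a + b + c == 0 else (b + c) / (a + b + c)


def welch_p(group1, group2) -> float:
    """Two-sided Welch t-test p-value from the Welch–Satterthwaite formulas."""
    from scipy.special import stdtr
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (g1.mean() - g2.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * float(stdtr(df, -abs(t)))


def summary_fold(values) -> dict:
    """Brute-force mean/SD(n−1)/min/max/CV fold over a list."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return {"n": n, "mean": mean, "sd": sd, "min": min(values), "max": max(values),
            "cv": 100.0 * sd / mean if mean > 0 else None}
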