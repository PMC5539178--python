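"""Independent brute-force reference implementations used only by tests.

Each function follows the defining formula as literally as possible
(explicit sums of products, explicit masks, explicit ANOVA sums of
squares), deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_sumprod(x, y) -> float:
    """Pearson correlation via explicit sums of products."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def brute_lofc(data: np.ndarray) -> np.ndarray:
    t, n = data.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pearson_sumprod(data[:, i], data[:, j])
    return out


def brute_fisher_z(r, eps: float = 1e-7):
    r = np.clip(np.asarray(r, dtype=float), -1 + eps, 1 - eps)
    return 0.5 * np.log((1 + r) / (1 - r))


def brute_thofc(lofc: np.ndarray) -> np.ndarray:
    """z-score the matrix, drop rows i and j from both profiles, Pearson."""
    n = lofc.shape[0]
    z = brute_fisher_z(lofc)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ks = [k for k in range(n) if k not in (i, j)]
            out[i, j] = pearson_sumprod(z[i, ks], z[j, ks])
    return out


def brute_ahofc(lofc: np.ndarray, thofc: np.ndarray) -> np.ndarray:
    n = lofc.shape[0]
    zt = brute_fisher_z(thofc)
    zl = brute_fisher_z(lofc)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ks = [k for k in range(n) if k not in (i, j)]
            out[i, j] = pearson_sumprod(zt[i, ks], zl[j, ks])
    return out


def brute_dlofc(xi, xl, omega: int, step: int = 1) -> np.ndarray:
    """Windowed Pearson correlation, one window at a time."""
    T = len(xi)
    starts = range(0, T - omega + 1, step)
    return np.array(
        [pearson_sumprod(xi[s : s + omega], xl[s : s + omega]) for s in starts]
    )


def anova_icc(table: np.ndarray) -> float:
    """One-way ANOVA ICC with sums of squares written out; no clamping."""
    table = np.asarray(table, dtype=float)
    s, k = table.shape
    grand = table.sum() / (s * k)
    row_means = [sum(table[i]) / k for i in range(s)]
    ss_between = k * sum((m - grand) ** 2 for m in row_means)
    ss_within = sum(
        (table[i, j] - row_means[i]) ** 2 for i in range(s) for j in range(k)
    )
    ms_b = ss_between / (s - 1)
    ms_w = ss_within / (s * (k - 1))
    return (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)


def brute_mann_whitney_u(a, b) -> float:
    """U statistic by direct pairwise comparison counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_u_pvalue(u_obs: float, n1: int, n2: int) -> float:
    """Two-sided exact p-value of the U statistic by full enumeration of
    rank assignments (feasible only for tiny n1 + n2)."""
    total = n1 + n2
    counts: dict[float, int] = {}
    for combo in itertools.combinations(range(total), n1):
        ranks_a = set(combo)
        u = sum(1 for i in ranks_a for j in range(total) if j not in ranks_a and i > j)
        counts[u] = counts.get(u, 0) + 1
    n_total = sum(counts.values())
    mean_u = n1 * n2 / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(c for u, c in counts.items() if abs(u - mean_u) >= dev - 1e-12)
    return extreme / n_total
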