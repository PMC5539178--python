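"""Test-retest reliability: one-way ICC, category summaries, and comparisons.

The estimator is the one-way random-effects intra-class correlation

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) * MS_w)

with MS_b the between-subject and MS_w the within-subject (between-session)
mean square, and k the number of repeated sessions. Negative estimates are
clamped to zero. Categories: poor [0, 0.2), fair [0.2, 0.4), moderate
[0.4, 0.6), good [0.6, 0.8), excellent [0.8, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ConnectivityMatrix

__all__ = [
    "ReliabilityMap",
    "icc_oneway",
    "icc_map",
    "categorize_icc",
    "summarize_reliability",
    "icc_difference",
    "regional_icc_gain",
    "compare_top_links",
    "ICC_BINS",
]

log = logging.getLogger(__name__)

#: Category edges; bins are left-closed, the last bin closed on both sides.
ICC_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
ICC_CATEGORIES = ("poor", "fair", "moderate", "good", "excellent")


@dataclass(frozen=True)
class ReliabilityMap:
    """Per-connection ICC values aligned to a connectivity matrix layout."""

    icc: np.ndarray
    metric: str
    roi_ids: tuple[str, ...] = ()
    n_used: np.ndarray | None = None

    @property
    def symmetric(self) -> bool:
        return self.metric != "aHOFC"

    def categories(self) -> np.ndarray:
        flat = [categorize_icc(v) for v in self.icc.ravel()]
        return np.asarray(flat, dtype=object).reshape(self.icc.shape)

    def connection_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to unique off-diagonal connections (upper triangle when
        symmetric, all off-diagonal cells otherwise), optionally masked."""
        n = self.icc.shape[0]
        if self.symmetric:
            sel = np.triu(np.ones((n, n), dtype=bool), k=1)
        else:
            sel = ~np.eye(n, dtype=bool)
        if mask is not None:
            sel = sel & mask
        return self.icc[sel]


def _oneway_ms(table: np.ndarray) -> tuple[float, float, int]:
    """Between- and within-subject mean squares of a subjects x sessions table."""
    s, k = table.shape
    subj_means = table.mean(axis=1)
    grand = table.mean()
    ss_b = k * np.sum((subj_means - grand) ** 2)
    ss_w = np.sum((table - subj_means[:, None]) ** 2)
    ms_b = ss_b / (s - 1)
    ms_w = ss_w / (s * (k - 1))
    return ms_b, ms_w, k


def icc_oneway(table: np.ndarray) -> float:
    """One-way ICC of one connection's subjects x sessions measurement table.

    Rows containing NaN are dropped (logged); with fewer than 2 complete
    rows, or zero total variance, the result is NaN.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("measurement table must be 2-D (subjects x sessions)")
    if arr.shape[1] < 2:
        raise ValueError("k >= 2 sessions required")
    keep = ~np.isnan(arr).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("icc_oneway: dropped %d subject rows containing NaN", dropped)
    arr = arr[keep]
    if arr.shape[0] < 2:
        log.warning("icc_oneway: fewer than 2 complete subjects; ICC undefined")
        return float("nan")
    ms_b, ms_w, k = _oneway_ms(arr)
    # numerically-zero total variance (relative to the data scale) is
    # undefined, not perfectly reliable: grand-mean rounding can leave
    # MS_b at ~1e-30 for a constant table
    scale = max(float(np.abs(arr).max()), 1.0)
    tol = arr.size * (16 * np.finfo(float).eps * scale) ** 2
    if (s := arr.shape[0]) and (ms_b * (s - 1) + ms_w * s * (k - 1)) <= tol:
        log.warning("icc_oneway: zero total variance; ICC undefined")
        return float("nan")
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    return float(max(icc, 0.0))


def icc_map(
    matrices: Sequence[Sequence[ConnectivityMatrix]] | np.ndarray,
    metric: str | None = None,
) -> ReliabilityMap:
    """Per-connection ICC over a complete subjects x sessions design.

    ``matrices`` is either a nested sequence ``[subject][session]`` of
    ``ConnectivityMatrix`` (all same metric and shape) or a raw array of
    shape (S, k, N, N). Each connection's ICC is computed independently; the
    diagonal is NaN.
    """
    if isinstance(matrices, np.ndarray):
        stack = matrices.astype(float)
        roi_ids: tuple[str, ...] = ()
        metric = metric or "ICC"
    else:
        first = matrices[0][0]
        metric = metric or first.metric
        roi_ids = first.roi_ids
        k = len(matrices[0])
        if any(len(row) != k for row in matrices):
            raise ValueError("incomplete subject x session design")
        for row in matrices:
            for m in row:
                if m.values.shape != first.values.shape:
                    raise ValueError("matrix shape mismatch in design")
        stack = np.stack([np.stack([m.values for m in row]) for row in matrices])
    s, k, n, _ = stack.shape
    if s < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")

    # vectorized one-way ANOVA over all N*N connections at once
    flat = stack.reshape(s, k, n * n)
    valid = ~np.isnan(flat).any(axis=1)          # (s, conn) complete rows
    n_used = valid.sum(axis=0)
    x = np.where(valid[:, None, :], flat, 0.0)
    cnt = n_used[None, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        subj_mean = x.mean(axis=1)                                  # (s, conn)
        grand = x.sum(axis=(0, 1)) / (n_used * k)                   # (conn,)
        ss_b = k * np.sum(
            np.where(valid, (subj_mean - grand[None, :]) ** 2, 0.0), axis=0
        )
        ss_w = np.sum(
            np.where(valid[:, None, :], (x - subj_mean[:, None, :]) ** 2, 0.0),
            axis=(0, 1),
        )
        ms_b = ss_b / (n_used - 1)
        ms_w = ss_w / (n_used * (k - 1))
        icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    # numerically-zero total variance (relative to data scale) is undefined
    scale = np.maximum(np.where(valid[:, None, :], np.abs(x), 0.0).max(axis=(0, 1)), 1.0)
    tol = (n_used * k) * (16 * np.finfo(float).eps * scale) ** 2
    icc = np.where((ss_b + ss_w) <= tol, np.nan, icc)
    icc = np.where(n_used < 2, np.nan, icc)
    icc = np.maximum(icc, 0.0)
    icc = icc.reshape(n, n)
    np.fill_diagonal(icc, np.nan)
    n_used = n_used.reshape(n, n)
    return ReliabilityMap(icc, metric, roi_ids, n_used)


def categorize_icc(icc: float) -> str:
    """Category label for one ICC value; NaN maps to 'undefined'."""
    if np.isnan(icc):
        return "undefined"
    if icc < 0.0 or icc > 1.0:
        raise ValueError(f"ICC {icc} outside [0, 1]")
    for lo, hi, name in zip(ICC_BINS[:-1], ICC_BINS[1:], ICC_CATEGORIES):
        if lo <= icc < hi:
            return name
    return "excellent"  # icc == 1.0


def summarize_reliability(
    rmap: ReliabilityMap, mask: np.ndarray | None = None
) -> dict:
    """Counts, percentages per category and the fraction with ICC > 0.2.

    Computed over unique off-diagonal connections (optionally masked);
    undefined (NaN) connections are counted separately and excluded from the
    percentages.
    """
    vals = rmap.connection_values(mask)
    if vals.size == 0:
        raise ValueError("empty connection mask")
    defined = vals[~np.isnan(vals)]
    counts = {c: 0 for c in ICC_CATEGORIES}
    for v in defined:
        counts[categorize_icc(v)] += 1
    total = len(defined)
    percentages = {
        c: (100.0 * counts[c] / total if total else float("nan")) for c in counts
    }
    frac = float(np.mean(defined > 0.2)) if total else float("nan")
    return {
        "n_connections": int(vals.size),
        "n_defined": int(total),
        "n_undefined": int(vals.size - total),
        "counts": counts,
        "percentages": percentages,
        "fraction_above_0.2": frac,
        "mean_icc": float(defined.mean()) if total else float("nan"),
        "median_icc": float(np.median(defined)) if total else float("nan"),
    }


def icc_difference(map_a: ReliabilityMap, map_b: ReliabilityMap) -> np.ndarray:
    """Element-wise ICC difference (a - b); NaN where either side is NaN."""
    if map_a.icc.shape != map_b.icc.shape:
        raise ValueError("reliability maps have different shapes")
    return map_a.icc - map_b.icc


def regional_icc_gain(
    diff: np.ndarray, roi_ids: Sequence[str] | None = None, symmetric: bool | None = None
) -> dict[str, float]:
    """Per-region sum of positive ICC increments over incident connections.

    Negative differences contribute nothing. For a symmetric difference
    matrix each unordered connection is counted once (row sum); for an
    asymmetric one both the row and the column entries incident to a region
    are counted. Symmetry is auto-detected unless given.
    """
    d = np.asarray(diff, dtype=float)
    n = d.shape[0]
    ids = list(roi_ids) if roi_ids else [f"R{i + 1}" for i in range(n)]
    if symmetric is None:
        symmetric = bool(np.allclose(np.nan_to_num(d), np.nan_to_num(d.T)))
    pos = np.where(np.isnan(d), 0.0, np.maximum(d, 0.0))
    np.fill_diagonal(pos, 0.0)
    if symmetric:
        gains = pos.sum(axis=1)
    else:
        gains = pos.sum(axis=1) + pos.sum(axis=0)
    return {r: float(g) for r, g in zip(ids, gains)}


def compare_top_links(
    values_a: np.ndarray, values_b: np.ndarray, n_top: int = 50
) -> dict:
    """Compare the ``n_top`` strongest connections of two metrics.

    Selects the n_top largest finite values of each input (ties broken by
    stable index order) and runs a two-sided Mann-Whitney U test. Returns
    the p-value, U statistic, and each group's mean and standard deviation.
    """
    out = {}
    tops = []
    for name, v in (("a", values_a), ("b", values_b)):
        v = np.asarray(v, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size < n_top:
            raise ValueError(
                f"input {name} has {v.size} finite values, fewer than n_top={n_top}"
            )
        # stable selection: sort by (-value, index) so ties keep file order
        order = np.argsort(-v, kind="stable")[:n_top]
        top = v[order]
        tops.append(top)
        out[f"mean_{name}"] = float(top.mean())
        out[f"sd_{name}"] = float(top.std(ddof=1))
    a, b = tops
    if np.ptp(np.concatenate([a, b])) == 0.0:
        u, p = float(n_top * n_top / 2), 1.0  # all values tied
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    out["u_statistic"] = u
    out["p_value"] = p
    out["n_top"] = n_top
    return out
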