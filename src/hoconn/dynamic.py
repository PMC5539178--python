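"""Sliding-window dynamic LOFC and the dHOFC hyper-network.

dLOFC is the windowed Pearson correlation of a region pair's signals: with
window length omega (timepoints) and unit step there are T - omega + 1
windows. dHOFC correlates two such dLOFC time series, yielding a
quadruple-region "hyperlink" between two "hypernodes" (region pairs). For n
regions there are P = n(n-1)/2 hypernodes and P(P-1)/2 unique hyperlinks;
hypernode pairs sharing one region are legitimate hyperlinks, only the
self-hyperlink is excluded from summaries.

When two networks are declared, hyperlinks are typed by the network
membership of the four regions: within-network (both hypernodes intra-net,
same network), between-network (both intra-net, different networks), and
modulatory (case 1: both hypernodes inter-network; case 2: exactly one).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import NetworkAtlas, ROITimeSeries

__all__ = [
    "WindowSpec",
    "DLOFCSeries",
    "HyperNetwork",
    "window_starts",
    "compute_dlofc",
    "build_hypernodes",
    "compute_dhofc",
    "classify_hyperlink",
    "threshold_strong",
    "STRONG_DHOFC_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Default strong-connectivity cutoff for dynamic correlations; values below
#: this are plausibly sampling noise (Leonardi & Van De Ville's bound).
STRONG_DHOFC_THRESHOLD = 0.36

WITHIN_NETWORK = "within_network"
BETWEEN_NETWORK = "between_network"
MODULATORY_CASE1 = "modulatory_case1"
MODULATORY_CASE2 = "modulatory_case2"
UNTYPED = "untyped"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters in timepoints: length ``omega``, stride ``step``."""

    omega: int = 30
    step: int = 1

    def __post_init__(self) -> None:
        if self.omega < 2:
            raise ValueError("omega >= 2 required")
        if self.step < 1:
            raise ValueError("step >= 1 required")

    def n_windows(self, T: int) -> int:
        if self.omega > T:
            raise ValueError(f"omega={self.omega} exceeds T={T}")
        return (T - self.omega) // self.step + 1

    def seconds(self, tr_seconds: float) -> float:
        return self.omega * tr_seconds


@dataclass(frozen=True)
class DLOFCSeries:
    """Windowed correlation time series for one region pair."""

    pair: tuple[str, str]
    values: np.ndarray
    spec: WindowSpec


@dataclass(frozen=True)
class HyperNetwork:
    """P x P dHOFC matrix over hypernodes (region pairs).

    ``hypernodes`` is the ordered pair list; ``pair_index`` maps an unordered
    pair to its row. The diagonal is 1 by convention and excluded from all
    summaries. ``hyperlink_types`` is present when two networks were declared.
    """

    roi_subset: tuple[str, ...]
    hypernodes: tuple[tuple[str, str], ...]
    values: np.ndarray
    hyperlink_types: np.ndarray | None = None
    pair_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.pair_index:
            object.__setattr__(
                self,
                "pair_index",
                {frozenset(p): k for k, p in enumerate(self.hypernodes)},
            )

    @property
    def n_hypernodes(self) -> int:
        return len(self.hypernodes)

    @property
    def n_unique_hyperlinks(self) -> int:
        p = self.n_hypernodes
        return p * (p - 1) // 2

    def hyperlink(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        return float(
            self.values[self.pair_index[frozenset(pair1)], self.pair_index[frozenset(pair2)]]
        )


def window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    """0-based window start indices; errors if fewer than 3 windows result."""
    w = spec.n_windows(T)
    if w < 3:
        raise ValueError(
            f"too few windows for dHOFC correlation (W={w} < 3 with T={T}, "
            f"omega={spec.omega}, step={spec.step})"
        )
    return np.arange(w) * spec.step


def _windowed_corr_matrix(x: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """All-pairs windowed Pearson correlations.

    Returns an array of shape (W, N, N) via cumulative sums, O(T N^2).
    Zero-variance windows give NaN for the pairs involved.
    """
    T, n = x.shape
    starts = window_starts(T, spec)
    om = spec.omega

    cs = np.concatenate([np.zeros((1, n)), np.cumsum(x, axis=0)])
    csq = np.concatenate([np.zeros((1, n)), np.cumsum(x**2, axis=0)])
    s1 = cs[starts + om] - cs[starts]            # (W, N) window sums
    s2 = csq[starts + om] - csq[starts]          # (W, N) window sums of squares

    # cross products: cumulate x_i * x_j for each pair via einsum per window
    cross = np.einsum("ti,tj->tij", x, x)
    ccross = np.concatenate([np.zeros((1, n, n)), np.cumsum(cross, axis=0)])
    sxy = ccross[starts + om] - ccross[starts]   # (W, N, N)

    mean = s1 / om
    cov = sxy / om - np.einsum("wi,wj->wij", mean, mean)
    var = s2 / om - mean**2
    var = np.maximum(var, 0.0)
    den = np.sqrt(np.einsum("wi,wj->wij", var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, cov / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def compute_dlofc(
    ts: ROITimeSeries, i: str, l: str, spec: WindowSpec = WindowSpec()
) -> DLOFCSeries:
    """Windowed Pearson correlation between regions ``i`` and ``l``."""
    if i == l:
        raise ValueError("dLOFC requires two distinct regions")
    idx = {r: j for j, r in enumerate(ts.roi_ids)}
    xi = ts.data[:, idx[i]]
    xl = ts.data[:, idx[l]]
    starts = window_starts(ts.n_timepoints, spec)
    vals = np.empty(len(starts))
    for w, s in enumerate(starts):
        a = xi[s : s + spec.omega]
        b = xl[s : s + spec.omega]
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            vals[w] = np.nan
        else:
            vals[w] = np.corrcoef(a, b)[0, 1]
    if np.isnan(vals).any():
        log.warning(
            "zero-variance windows produced NaN dLOFC for pair (%s, %s)", i, l
        )
    return DLOFCSeries((i, l), np.clip(vals, -1.0, 1.0), spec)


def build_hypernodes(
    roi_subset: Sequence[str],
    atlas: NetworkAtlas | None = None,
    networks: tuple[str, str] | None = None,
) -> tuple[tuple[str, str], ...]:
    """Ordered hypernode (region-pair) list for a region subset.

    Without an atlas the n(n-1)/2 pairs (i < l by subset position) are in
    plain lexicographic order. With an atlas and two declared networks they
    are grouped into blocks — intra-net1, intra-net2, then inter-network —
    lexicographic within each block, matching the conventional hyper-matrix
    layout for two-system analyses.
    """
    rois = list(roi_subset)
    if len(set(rois)) != len(rois):
        raise ValueError("duplicate region ids in roi_subset")
    if len(rois) < 3:
        raise ValueError("need at least 3 regions to form a hyper-network")
    pairs = list(itertools.combinations(rois, 2))
    if atlas is None or networks is None:
        return tuple(pairs)
    net1, net2 = networks
    blocks: dict[str, list[tuple[str, str]]] = {"n1": [], "n2": [], "inter": [], "other": []}
    for a, b in pairs:
        na, nb = atlas.network_of(a), atlas.network_of(b)
        if na == net1 and nb == net1:
            blocks["n1"].append((a, b))
        elif na == net2 and nb == net2:
            blocks["n2"].append((a, b))
        elif {na, nb} == {net1, net2}:
            blocks["inter"].append((a, b))
        else:
            blocks["other"].append((a, b))
    if blocks["other"]:
        log.warning("%d pairs involve undeclared networks", len(blocks["other"]))
    return tuple(blocks["n1"] + blocks["n2"] + blocks["inter"] + blocks["other"])


def compute_dhofc(
    ts: ROITimeSeries,
    roi_subset: Sequence[str],
    spec: WindowSpec = WindowSpec(),
    atlas: NetworkAtlas | None = None,
    networks: tuple[str, str] | None = None,
) -> HyperNetwork:
    """The dHOFC hyper-network over all region pairs of ``roi_subset``.

    All dLOFC series use the same window specification; the P x P matrix is
    the Pearson correlation between dLOFC series, symmetric with unit
    diagonal. Any all-NaN dLOFC series NaNs out its row/column (logged).
    """
    hypernodes = build_hypernodes(roi_subset, atlas, networks)
    sub = ts.subset(roi_subset)
    pos = {r: j for j, r in enumerate(sub.roi_ids)}
    wr = _windowed_corr_matrix(sub.data, spec)  # (W, n, n)
    series = np.stack([wr[:, pos[a], pos[b]] for a, b in hypernodes])  # (P, W)

    bad = np.isnan(series).any(axis=1)
    if bad.any():
        log.warning("%d dLOFC series contain NaN; their hyperlinks are NaN", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        dh = np.corrcoef(series)
    dh = np.clip(dh, -1.0, 1.0)
    dh[bad, :] = np.nan
    dh[:, bad] = np.nan
    np.fill_diagonal(dh, 1.0)
    dh = (dh + dh.T) / 2.0

    types = None
    if atlas is not None and networks is not None:
        p = len(hypernodes)
        types = np.full((p, p), UNTYPED, dtype=object)
        kinds = [_hypernode_kind(pair, atlas, networks) for pair in hypernodes]
        for a in range(p):
            for b in range(p):
                types[a, b] = _type_from_kinds(kinds[a], kinds[b])
    return HyperNetwork(tuple(roi_subset), hypernodes, dh, types)


def _hypernode_kind(
    pair: tuple[str, str], atlas: NetworkAtlas, networks: tuple[str, str]
) -> str:
    na, nb = atlas.network_of(pair[0]), atlas.network_of(pair[1])
    net1, net2 = networks
    if na not in networks or nb not in networks:
        return "other"
    if na == nb:
        return "intra1" if na == net1 else "intra2"
    return "inter"


def _type_from_kinds(ka: str, kb: str) -> str:
    if ka == "other" or kb == "other":
        return UNTYPED
    inter_count = (ka == "inter") + (kb == "inter")
    if inter_count == 2:
        return MODULATORY_CASE1
    if inter_count == 1:
        return MODULATORY_CASE2
    return WITHIN_NETWORK if ka == kb else BETWEEN_NETWORK


def classify_hyperlink(
    pair1: tuple[str, str],
    pair2: tuple[str, str],
    atlas: NetworkAtlas,
    networks: tuple[str, str],
) -> str:
    """Type of the hyperlink between two hypernodes under two declared networks."""
    ka = _hypernode_kind(pair1, atlas, networks)
    kb = _hypernode_kind(pair2, atlas, networks)
    if ka == "other" or kb == "other":
        log.warning("hyperlink involves a region from an undeclared network")
    return _type_from_kinds(ka, kb)


def threshold_strong(
    values: HyperNetwork | np.ndarray, threshold: float = STRONG_DHOFC_THRESHOLD
) -> np.ndarray:
    """Boolean mask of strong hyperlinks: value strictly above ``threshold``.

    ``values`` is typically the group-mean dHOFC matrix. The diagonal is
    always False; NaN compares False.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    arr = values.values if isinstance(values, HyperNetwork) else np.asarray(values)
    with np.errstate(invalid="ignore"):
        mask = arr > threshold
    np.fill_diagonal(mask, False)
    return mask
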