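"""Static pairwise connectivity metrics: LOFC, tHOFC and aHOFC.

LOFC (low-order functional connectivity) is the plain Pearson correlation
between two regions' full-length signals. tHOFC (topographical-profile
high-order FC) correlates, for a pair (i, j), the two regions' Fisher
z-transformed LOFC profiles over all third regions k != i, j — "correlation
of correlations". aHOFC correlates region i's z-transformed tHOFC profile
with region j's z-transformed LOFC profile over the same k, measuring the
association between the low- and high-order connectivity levels; it is not
symmetric in general and its diagonal (self-association) is set to zero.

For an N-region parcellation each profile has length N - 2: the two
self-connections of the pair under evaluation are excluded from both
profiles, keeping them aligned.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import ConnectivityMatrix, ROITimeSeries

__all__ = ["compute_lofc", "fisher_z", "compute_thofc", "compute_ahofc"]

log = logging.getLogger(__name__)

#: Clamp radius for Fisher's transform: |r| >= 1 - FISHER_EPS is pulled to the
#: boundary so perfect correlations stay finite without shifting moderate ones.
FISHER_EPS = 1e-7


def compute_lofc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of every region pair over the full time series.

    Columns with zero variance yield NaN in every entry involving that
    region (logged), rather than being dropped silently. The diagonal is
    exactly 1 and off-diagonal entries are clipped into [-1, 1] against
    floating-point overshoot.
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("T >= 3 required for LOFC")
    sd = x.std(axis=0)
    degenerate = np.flatnonzero(sd == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if degenerate.size:
        bad = [ts.roi_ids[j] for j in degenerate]
        log.warning("zero-variance regions set to NaN in LOFC: %s", bad)
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
        for j in degenerate:
            r[j, j] = 1.0
    return ConnectivityMatrix(r, "LOFC", ts.roi_ids)


def fisher_z(r):
    """Fisher r-to-z transform, z = arctanh(r), with |r| clamped to 1 - 1e-7.

    Accepts a scalar or an array; NaN passes through. Raises on |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr) > 1.0):
            raise ValueError("|r| > 1 is outside the correlation domain")
    out = np.arctanh(np.clip(arr, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(r) else out


def _pair_profile_corr(zu: np.ndarray, zv: np.ndarray) -> np.ndarray:
    """Correlation of row-profiles of ``zu`` and ``zv`` excluding, for each
    pair (i, j), the entries at columns i and j from both profiles.

    Two-pass (center, then accumulate products) per pair for numerical
    accuracy; rows containing NaN propagate NaN to every pair touching
    them, and degenerate (zero-variance) profiles yield NaN.
    """
    n = zu.shape[0]
    out = np.full((n, n), np.nan)
    idx = np.arange(n)
    with np.errstate(invalid="ignore"):
        for i in range(n):
            mask_i = idx != i
            for j in range(n):
                if i == j:
                    continue
                mask = mask_i & (idx != j)
                u = zu[i, mask]
                v = zv[j, mask]
                u = u - u.mean()
                v = v - v.mean()
                den = np.sqrt((u @ u) * (v @ v))
                if den > 0:
                    out[i, j] = (u @ v) / den
    return np.clip(out, -1.0, 1.0)


def compute_thofc(lofc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Topographical-profile HOFC from an LOFC matrix.

    The LOFC values are Fisher z-transformed first; for each pair (i, j) the
    two length-(N-2) profiles over k != i, j are Pearson-correlated. Output
    is symmetric with unit diagonal.
    """
    if lofc.metric != "LOFC":
        raise ValueError("compute_thofc expects an LOFC matrix")
    n = lofc.n_regions
    if n < 5:
        # length-(N-2) profiles need at least 3 entries for a meaningful
        # correlation; at N = 4 every profile correlation degenerates to +/-1
        raise ValueError("profiles too short for correlation (need N >= 5)")
    _warn_nan(lofc.values, "tHOFC")
    z = fisher_z(lofc.values)
    r = _pair_profile_corr(z, z)
    r = (r + r.T) / 2.0  # symmetric by formula; average away rounding skew
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, "tHOFC", lofc.roi_ids)


def compute_ahofc(
    lofc: ConnectivityMatrix, thofc: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Associated HOFC: cross-level profile correlation.

    Entry (i, j) correlates region i's z-transformed tHOFC profile with
    region j's z-transformed LOFC profile over k != i, j. The matrix is NOT
    symmetrized and the diagonal (self-associated HOFC) is set to zero.
    """
    if lofc.values.shape != thofc.values.shape:
        raise ValueError("LOFC and tHOFC shapes differ")
    if lofc.n_regions < 5:
        raise ValueError("profiles too short for correlation (need N >= 5)")
    _warn_nan(lofc.values, "aHOFC")
    zt = fisher_z(thofc.values)
    zl = fisher_z(lofc.values)
    r = _pair_profile_corr(zt, zl)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, "aHOFC", lofc.roi_ids)


def _warn_nan(values: np.ndarray, what: str) -> None:
    if np.isnan(values).any():
        log.warning(
            "%s input contains NaN entries; affected pairs propagate NaN", what
        )
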