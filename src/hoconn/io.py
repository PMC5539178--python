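"""Reading, writing and validation of ROI time series, atlases and matrices.

All interchange is delimited text (TSV by default): time series are stored
with timepoints as rows and regions as columns, optionally with a header row
of region identifiers; connectivity and reliability matrices are stored with
row/column labels. ROI indices are 1-based in files and reports, 0-based
internally — the boundary is this module.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "ROITimeSeriesSet",
    "NetworkAtlas",
    "ConnectivityMatrix",
    "ValidationReport",
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
    "bundled_atlas",
    "read_matrix",
    "write_matrix",
    "validate_set",
]

#: Metrics whose matrices are symmetric by construction.
SYMMETRIC_METRICS = frozenset({"LOFC", "tHOFC", "dHOFC", "ICC", "ICC_DIFF"})
KNOWN_METRICS = frozenset({"LOFC", "tHOFC", "aHOFC", "dHOFC", "ICC", "ICC_DIFF"})

#: Network labels of the bundled region table (hand sensorimotor plus the two
#: high-level cognitive systems used for hyper-network construction).
ATLAS_NETWORKS = (
    "Sensorimotor Hand",
    "Fronto-parietal Control",
    "Salience Network",
)


class StructureError(ValueError):
    """Malformed file layout (ragged rows, missing/unknown columns)."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


@dataclass(frozen=True)
class ROITimeSeries:
    """A single scan: T timepoints (rows) by N regions (columns).

    Parameters
    ----------
    data : ndarray, shape (T, N)
        BOLD-like signal values, arbitrary units.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    roi_ids : tuple of str
        Ordered, unique region identifiers, length N.
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    roi_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise StructureError("time series must be a 2-D array (T x N)")
        if arr.shape[0] < 2:
            raise ValueError("T >= 2 required")
        if arr.shape[1] < 2:
            raise ValueError("N >= 2 required")
        if not np.isfinite(arr).all():
            raise ValueError("time series contains missing/non-finite values")
        ids = self.roi_ids or tuple(f"R{i + 1}" for i in range(arr.shape[1]))
        if len(ids) != arr.shape[1]:
            raise ValueError("roi_ids length must equal number of columns")
        if len(set(ids)) != len(ids):
            raise ValueError("roi_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "roi_ids", tuple(ids))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def subset(self, roi_ids: Sequence[str]) -> "ROITimeSeries":
        """Restrict to the given regions, in the given order."""
        index = {r: j for j, r in enumerate(self.roi_ids)}
        missing = [r for r in roi_ids if r not in index]
        if missing:
            raise KeyError(f"unknown roi_ids: {missing}")
        cols = [index[r] for r in roi_ids]
        return ROITimeSeries(self.data[:, cols], self.tr_seconds, tuple(roi_ids))


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    missing_cells: tuple[tuple[str, str], ...] = ()
    mismatches: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.valid:
            return "valid multi-session set"
        lines = ["invalid multi-session set:"]
        lines += [f"  missing cell: subject={s} session={e}" for s, e in self.missing_cells]
        lines += [f"  {m}" for m in self.mismatches]
        return "\n".join(lines)


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Complete subject-by-session collection of scans with identical layout."""

    entries: Mapping[tuple[str, str], ROITimeSeries]
    subjects: tuple[str, ...]
    sessions: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "sessions", tuple(self.sessions))
        report = validate_set(self)
        if not report.valid:
            raise ValueError(str(report))

    @property
    def roi_ids(self) -> tuple[str, ...]:
        first = next(iter(self.entries.values()))
        return first.roi_ids

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.entries.values())).n_timepoints

    def get(self, subject: str, session: str) -> ROITimeSeries:
        return self.entries[(subject, session)]


def validate_set(tset: ROITimeSeriesSet | Mapping, subjects=None, sessions=None) -> ValidationReport:
    """Check a subject x session design for completeness and shape consistency.

    Accepts either an ``ROITimeSeriesSet`` or a raw mapping plus explicit
    subject/session lists (used before construction).
    """
    if isinstance(tset, ROITimeSeriesSet):
        entries, subjects, sessions = tset.entries, tset.subjects, tset.sessions
    else:
        entries = tset
        subjects = tuple(subjects or ())
        sessions = tuple(sessions or ())
    missing = [
        (s, e) for s in subjects for e in sessions if (s, e) not in entries
    ]
    mismatches: list[str] = []
    ref: ROITimeSeries | None = None
    for (s, e), ts in entries.items():
        if ref is None:
            ref = ts
            continue
        if ts.roi_ids != ref.roi_ids:
            mismatches.append(f"subject={s} session={e}: roi_ids differ from first entry")
        if ts.n_timepoints != ref.n_timepoints:
            mismatches.append(
                f"subject={s} session={e}: T={ts.n_timepoints} != {ref.n_timepoints}"
            )
    return ValidationReport(
        valid=not missing and not mismatches,
        missing_cells=tuple(missing),
        mismatches=tuple(mismatches),
    )


@dataclass(frozen=True)
class NetworkAtlas:
    """ROI lookup table: 1-based index, original atlas index, MNI mm, network."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("roi_index", "orig_index", "x", "y", "z", "network")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise StructureError(f"atlas missing required columns: {missing}")
        extra = [c for c in df.columns if c not in self.REQUIRED]
        if extra:
            raise StructureError(f"atlas has unknown columns: {extra}")
        if len(df) == 0:
            raise ValueError("atlas is empty")
        idx = df["roi_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate roi_index in atlas")
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(np.sort(idx), expected):
            raise ValueError("roi_index must be contiguous from 1")
        object.__setattr__(self, "table", df.sort_values("roi_index").reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> tuple[str, ...]:
        seen: list[str] = []
        for n in self.table["network"]:
            if n not in seen:
                seen.append(n)
        return tuple(seen)

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(f"R{int(i)}" for i in self.table["roi_index"])

    def network_of(self, roi_id: str) -> str:
        idx = int(roi_id.lstrip("R")) - 1
        return str(self.table["network"].iloc[idx])

    def rois_in(self, network: str) -> tuple[str, ...]:
        mask = self.table["network"] == network
        return tuple(f"R{int(i)}" for i in self.table.loc[mask, "roi_index"])

    def network_counts(self) -> dict[str, int]:
        return self.table["network"].value_counts().to_dict()


@dataclass(frozen=True)
class ConnectivityMatrix:
    """An N x N matrix of one connectivity or reliability metric.

    LOFC and tHOFC are symmetric with unit diagonal; aHOFC is generally
    asymmetric with a zero diagonal; ICC maps live in [0, 1].
    """

    values: np.ndarray
    metric: str
    roi_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.metric not in KNOWN_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        ids = self.roi_ids or tuple(f"R{i + 1}" for i in range(arr.shape[0]))
        if len(ids) != arr.shape[0]:
            raise ValueError("roi_ids length must match matrix size")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "roi_ids", tuple(ids))

    @property
    def symmetric(self) -> bool:
        return self.metric in SYMMETRIC_METRICS

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: str | Path, delimiter: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            rows.append(line.split(delimiter))
    return rows


def read_timeseries(
    path: str | Path, delimiter: str = "\t", tr_seconds: float = 2.0
) -> ROITimeSeries:
    """Read a T x N time-series table; a non-numeric first row is the header."""
    rows = _read_table(path, delimiter)
    if not rows:
        raise StructureError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise StructureError(f"{path}: ragged rows (widths {sorted(widths)})")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    ncols = next(iter(widths))
    roi_ids: tuple[str, ...] = ()
    if not all(_is_number(tok) for tok in rows[0]):
        roi_ids = tuple(rows[0])
        rows = rows[1:]
    data = np.empty((len(rows), ncols), dtype=float)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            try:
                data[i, j] = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell at data row {i + 1}, column {j + 1}: {tok!r}"
                ) from exc
    if data.shape[0] < 2:
        raise ValueError("T >= 2 required")
    return ROITimeSeries(data, tr_seconds=tr_seconds, roi_ids=roi_ids)


def write_timeseries(ts: ROITimeSeries, path: str | Path, delimiter: str = "\t") -> None:
    """Write a time series with header row, full decimal precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(ts.roi_ids) + "\n")
        for row in ts.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_atlas(path: str | Path, delimiter: str = "\t") -> NetworkAtlas:
    df = pd.read_csv(path, sep=delimiter)
    if len(df) == 0:
        raise ValueError(f"{path}: atlas is empty")
    return NetworkAtlas(df)


def write_atlas(atlas: NetworkAtlas, path: str | Path, delimiter: str = "\t") -> None:
    atlas.table.to_csv(path, sep=delimiter, index=False)


def bundled_atlas() -> NetworkAtlas:
    """The packaged 58-ROI table (26 hand-sensorimotor, 17 FPN, 15 SN regions)."""
    ref = importlib.resources.files("hoconn.data").joinpath("dhofc_roi_atlas.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_atlas(p)


def read_matrix(path: str | Path, metric: str, delimiter: str = "\t") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise StructureError(f"{path}: row labels differ from column labels")
    return ConnectivityMatrix(df.to_numpy(dtype=float), metric, tuple(str(c) for c in df.columns))


def write_matrix(mat: ConnectivityMatrix, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(("",) + mat.roi_ids) + "\n")
        for rid, row in zip(mat.roi_ids, mat.values):
            fh.write(delimiter.join((rid,) + tuple(repr(float(v)) for v in row)) + "\n")
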