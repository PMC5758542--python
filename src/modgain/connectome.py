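"""Functional-connectivity graph construction from ROI time series.

A subject's resting-state scan enters this module as a volumes x ROIs
matrix of averaged regional time series. From it we build the objects
the network metrics operate on:

* :class:`ConnectivityMatrix` — pairwise Pearson correlations between
  regional time series, optionally Fisher z-transformed (``atanh``),
  the variance-stabilized scale on which thresholding and averaging
  are performed;
* :class:`BinaryGraph` — an unweighted, undirected graph obtained by
  keeping the strongest ``floor(cost * M)`` connections out of the
  ``M = n(n-1)/2`` possible node pairs ("proportional" or "cost"
  thresholding), so every subject's graph has identical edge density.

Thresholding selects the largest *signed* z-values: at the sparse
densities used in practice (2–10%) this retains only strong positive
correlations. Selecting by absolute value is available via
``absolute=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "BinaryGraph",
    "correlation_matrix",
    "fisher_z",
    "proportional_threshold",
    "exclude_rois",
    "read_timeseries",
    "write_timeseries",
    "write_connectivity",
    "write_graph",
    "read_graph",
]


def _default_roi_ids(n: int) -> list[str]:
    return [f"roi{i:03d}" for i in range(n)]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """One subject's ROI time series (volumes x ROIs)."""

    values: np.ndarray
    roi_ids: tuple[str, ...]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D (volumes x ROIs) array")
        if values.shape[0] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if len(self.roi_ids) != values.shape[1]:
            raise ValueError(
                f"{len(self.roi_ids)} ROI labels for {values.shape[1]} columns"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("ROI labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        roi_ids: Sequence[str] | None = None,
        tr_seconds: float = 2.0,
    ) -> "TimeSeriesMatrix":
        values = np.asarray(values, dtype=float)
        if roi_ids is None:
            roi_ids = _default_roi_ids(values.shape[1])
        return cls(values=values, roi_ids=tuple(roi_ids), tr_seconds=tr_seconds)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI connectivity; ``scale`` is pearson_r or fisher_z.

    The diagonal is stored as zero and excluded from every downstream
    computation (thresholding, segregation averages).
    """

    values: np.ndarray
    scale: str
    roi_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_ids) != values.shape[0]:
            raise ValueError("ROI labels do not match matrix size")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        off = values[~np.eye(values.shape[0], dtype=bool)]
        if self.scale == "pearson_r" and off.size and np.max(np.abs(off)) > 1 + 1e-12:
            raise ValueError("Pearson correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted adjacency at a given connection density."""

    adjacency: np.ndarray
    cost: float
    roi_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.dtype != np.int8:
            adj = adj.astype(np.int8)
        object.__setattr__(self, "adjacency", adj)
        roi_ids = tuple(self.roi_ids) if self.roi_ids else tuple(_default_roi_ids(adj.shape[0]))
        object.__setattr__(self, "roi_ids", roi_ids)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not (0 < self.cost <= 1):
            raise ValueError("cost must lie in (0, 1]")
        if len(roi_ids) != adj.shape[0]:
            raise ValueError("ROI labels do not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between ROI time series.

    Requires at least 3 volumes and no constant column (a constant
    regional signal has undefined correlation and almost always marks a
    coverage failure upstream).
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to estimate correlations")
    sd = ts.values.std(axis=0)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        names = ", ".join(ts.roi_ids[i] for i in constant[:5])
        raise ValueError(f"constant time series for ROI(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, scale="pearson_r", roi_ids=ts.roi_ids)


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform, ``z = atanh(r)``, applied off-diagonal."""
    if cm.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    off = ~np.eye(cm.n_rois, dtype=bool)
    if np.any(np.abs(cm.values[off]) >= 1.0):
        i, j = np.unravel_index(
            np.argmax(np.abs(np.where(off, cm.values, 0.0))), cm.values.shape
        )
        raise ValueError(
            f"|r| = 1 between {cm.roi_ids[i]} and {cm.roi_ids[j]}: "
            "infinite z (duplicated ROI signals?)"
        )
    z = np.zeros_like(cm.values)
    z[off] = np.arctanh(cm.values[off])
    return ConnectivityMatrix(values=z, scale="fisher_z", roi_ids=cm.roi_ids)


def proportional_threshold(
    cm: ConnectivityMatrix, cost: float, absolute: bool = False
) -> BinaryGraph:
    """Binarize at a proportional density: keep the ``floor(cost * M)``
    strongest of the ``M = n(n-1)/2`` possible connections.

    Strength is the signed z-value by default (``absolute=True`` ranks by
    magnitude instead). Ties at the cutoff are broken by lexicographic
    (i, j) order so the edge set is deterministic and nested across costs.
    """
    if cm.scale != "fisher_z":
        raise ValueError("threshold the Fisher-z matrix, not raw correlations")
    if not (0 < cost <= 1):
        raise ValueError("cost must lie in (0, 1]")
    n = cm.n_rois
    m_possible = n * (n - 1) // 2
    k = int(np.floor(cost * m_possible))
    if k < 1:
        raise ValueError(
            f"cost {cost} yields 0 edges on {n} nodes; increase the density"
        )
    iu, ju = np.triu_indices(n, k=1)
    w = cm.values[iu, ju]
    if absolute:
        w = np.abs(w)
    # lexsort: last key is primary -> sort by descending weight, then (i, j)
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, cost=cost, roi_ids=cm.roi_ids)


def exclude_rois(obj, drop_list: Sequence[str]):
    """Drop ROIs by label from a TimeSeriesMatrix or ConnectivityMatrix.

    Survivor ordering is preserved. Unknown labels raise; dropping every
    ROI raises.
    """
    drop = set(drop_list)
    unknown = drop - set(obj.roi_ids)
    if unknown:
        raise KeyError(f"unknown ROI id(s): {sorted(unknown)[:5]}")
    keep_idx = [i for i, rid in enumerate(obj.roi_ids) if rid not in drop]
    if not keep_idx:
        raise ValueError("cannot drop every ROI")
    keep_ids = tuple(obj.roi_ids[i] for i in keep_idx)
    if isinstance(obj, TimeSeriesMatrix):
        return TimeSeriesMatrix(
            values=obj.values[:, keep_idx], roi_ids=keep_ids, tr_seconds=obj.tr_seconds
        )
    if isinstance(obj, ConnectivityMatrix):
        sub = obj.values[np.ix_(keep_idx, keep_idx)]
        return ConnectivityMatrix(values=sub, scale=obj.scale, roi_ids=keep_ids)
    raise TypeError(f"cannot exclude ROIs from {type(obj).__name__}")


# -- plain-text I/O ---------------------------------------------------------

def read_timeseries(path: str | Path, tr_seconds: float = 2.0) -> TimeSeriesMatrix:
    """Read a tab-delimited volumes x ROIs table with a header row of ROI ids."""
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        roi_ids=tuple(str(c) for c in df.columns),
        tr_seconds=tr_seconds,
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.roi_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.values, index=list(cm.roi_ids), columns=list(cm.roi_ids)).to_csv(
        path, float_format="%.10g"
    )


def write_graph(g: BinaryGraph, dense_path: str | Path | None = None,
                edgelist_path: str | Path | None = None) -> None:
    """Write a binary graph as a dense 0/1 CSV and/or a tab-delimited edge list."""
    if dense_path is not None:
        pd.DataFrame(
            g.adjacency, index=list(g.roi_ids), columns=list(g.roi_ids)
        ).to_csv(dense_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            for i, j in g.edge_list():
                fh.write(f"{g.roi_ids[i]}\t{g.roi_ids[j]}\n")


def read_graph(dense_path: str | Path, cost: float | None = None) -> BinaryGraph:
    df = pd.read_csv(dense_path, index_col=0)
    adj = df.to_numpy(dtype=np.int8)
    n = adj.shape[0]
    if cost is None:
        cost = (adj.sum() / 2) / (n * (n - 1) / 2)
    return BinaryGraph(adjacency=adj, cost=float(cost),
                       roi_ids=tuple(str(c) for c in df.columns))
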