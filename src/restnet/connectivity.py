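"""ROI time series -> Fisher-z connectivity matrices -> thresholded graphs.

Two thresholding routes are provided, mirroring how binary graph metrics and
weighted within/between-module connectivity are computed downstream:

* proportional density thresholding (top ``d`` fraction of the strongest
  connections, binarized), which equates edge counts across compared graphs;
* edge-wise FDR thresholding (Benjamini-Hochberg at level ``q``, separately
  for positive and negative edges), which keeps surviving signed weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "GraphView",
    "SignedWeightedGraph",
    "correlation_matrix",
    "threshold_density",
    "threshold_fdr",
    "read_timeseries",
    "read_matrix",
    "write_matrix",
    "write_edge_list",
]

_R_CLIP = 1.0 - 1e-7


def _check_square_symmetric(values: np.ndarray, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=1e-12, equal_nan=False):
        raise ValueError(f"{what} must be symmetric")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z ROI x ROI connectivity matrix with zero diagonal."""

    values: np.ndarray
    node_ids: tuple[str, ...]
    n_timepoints: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        _check_square_symmetric(v, "connectivity matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        if len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length does not match matrix size")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Density-thresholded unweighted graph (0/1 adjacency, zero diagonal)."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        _check_square_symmetric(a, "adjacency")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def view(self) -> "GraphView":
        return GraphView.from_graph(self)


@dataclass(frozen=True)
class GraphView:
    """Derived quantities of a binary graph: degrees k_i, the configuration
    null e_ij = k_i k_j / 2E, and all-pairs shortest hop counts L_ij
    (np.inf for disconnected pairs, 0 on the diagonal)."""

    degrees: np.ndarray
    null_model: np.ndarray
    shortest_path_lengths: np.ndarray

    @classmethod
    def from_graph(cls, graph: BinaryGraph) -> "GraphView":
        k = graph.degrees
        two_e = float(k.sum())
        null = np.outer(k, k) / two_e if two_e > 0 else np.zeros_like(
            graph.adjacency, dtype=float
        )
        lengths = shortest_path(
            np.asarray(graph.adjacency, dtype=float), method="D", unweighted=True
        )
        return cls(degrees=k, null_model=null, shortest_path_lengths=lengths)

    def neighbor_subgraph(self, adjacency: np.ndarray, node: int) -> np.ndarray:
        nbrs = np.flatnonzero(adjacency[node])
        return adjacency[np.ix_(nbrs, nbrs)]


@dataclass(frozen=True)
class SignedWeightedGraph:
    """FDR-retained signed weights; zeros where the edge test failed."""

    weights: np.ndarray
    q: float
    sign: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        _check_square_symmetric(w, "weights")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights diagonal must be zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def correlation_matrix(
    timeseries: "np.ndarray | pd.DataFrame",
    node_ids: "list[str] | None" = None,
) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs, Fisher-z transformed.

    ``timeseries`` is T x N (rows = time points). r is clipped to
    +/-(1 - 1e-7) before atanh so perfectly correlated columns stay finite;
    the diagonal is set to zero.
    """
    if isinstance(timeseries, pd.DataFrame):
        if node_ids is None:
            node_ids = [str(c) for c in timeseries.columns]
        ts = timeseries.to_numpy(dtype=float)
    else:
        ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D T x N array")
    t, n = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if node_ids is None:
        node_ids = [f"roi{j:03d}" for j in range(n)]
    if constant.size:
        names = ", ".join(node_ids[int(j)] for j in constant[:5])
        raise ValueError(f"constant time series for node(s): {names}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, node_ids=tuple(node_ids), n_timepoints=t)


def _edge_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices ordered by descending value; ties broken
    by ascending (i, j) lexicographic order for determinism."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    v = values[iu, ju]
    order = np.lexsort((ju, iu, -v))
    return iu[order], ju[order]


def threshold_density(C: ConnectivityMatrix, density: float) -> BinaryGraph:
    """Binarize by keeping the top ``density`` fraction of the strongest
    connections (K = round(d * N(N-1)/2), half-up)."""
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    n = C.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(density * n_pairs + 0.5))
    if k == 0:
        raise ValueError(
            f"density {density} retains 0 of {n_pairs} edges (degenerate graph)"
        )
    iu, ju = _edge_order(C.values)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density)


def threshold_fdr(
    C: ConnectivityMatrix,
    q: float = 0.05,
    sign: str = "positive",
    n_timepoints: "int | None" = None,
) -> SignedWeightedGraph:
    """Retain edges of the requested sign surviving Benjamini-Hochberg FDR.

    Two-sided p-values come from the Fisher-z normal approximation,
    z * sqrt(T - 3) against the standard normal; the step-up correction is
    applied across the edges of the requested sign only. Survivors keep
    their signed Fisher-z weight.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    t = n_timepoints if n_timepoints is not None else C.n_timepoints
    if t is None:
        raise ValueError("n_timepoints is required to convert Fisher-z to p-values")
    if t <= 3:
        raise ValueError("n_timepoints must exceed 3 for the z-approximation")
    n = C.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = C.values[iu, ju]
    mask = vals > 0 if sign == "positive" else vals < 0
    weights = np.zeros((n, n), dtype=float)
    if mask.any():
        z_stat = np.abs(vals[mask]) * np.sqrt(t - 3)
        pvals = 2.0 * stats.norm.sf(z_stat)
        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        keep_i, keep_j = iu[mask][reject], ju[mask][reject]
        weights[keep_i, keep_j] = vals[mask][reject]
        weights[keep_j, keep_i] = vals[mask][reject]
    return SignedWeightedGraph(weights=weights, q=q, sign=sign)


# ---------------------------------------------------------------------------
# file I/O

def read_timeseries(path: "Path | str") -> pd.DataFrame:
    """TSV time series, T rows x N columns, header row of node ids."""
    return pd.read_csv(path, sep="\t")


def read_matrix(path: "Path | str") -> ConnectivityMatrix:
    """Precomputed symmetric connectivity matrix (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    values = df.to_numpy(dtype=float)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, node_ids=tuple(map(str, df.columns)))


def write_matrix(values: np.ndarray, node_ids, path: "Path | str") -> None:
    pd.DataFrame(np.asarray(values), columns=list(node_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def write_edge_list(values: np.ndarray, node_ids, path: "Path | str") -> None:
    """Nonzero upper-triangle entries as CSV (node_i, node_j, weight)."""
    v = np.asarray(values)
    iu, ju = np.triu_indices(v.shape[0], k=1)
    keep = v[iu, ju] != 0
    ids = list(node_ids)
    pd.DataFrame(
        {
            "node_i": [ids[i] for i in iu[keep]],
            "node_j": [ids[j] for j in ju[keep]],
            "weight": v[iu, ju][keep],
        }
    ).to_csv(path, index=False, float_format="%.8g")
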