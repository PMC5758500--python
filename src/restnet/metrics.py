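"""Brain-wide and per-module graph metrics on binary graphs.

Modularity Q, global efficiency, per-node local efficiency and participation
coefficient, the consistent-node canonical module assignment used for
module-level comparisons across groups and sessions, FDR-weighted
within/between-module connectivity, and tidy per-subject metric tables
averaged across the density-threshold grid.

Conventions (shared with the brute-force oracles in the test suite):

* Q sums over ordered pairs including i = j (A_ii = 0, but the null term
  gamma * k_i^2 / 2E is counted) — the standard Newman convention.
* Local efficiency of nodes with fewer than 2 neighbors is 0, as is the
  participation coefficient of degree-0 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import shortest_path

from . import community as _community
from .community import ConsensusParams, Partition, weighted_modularity
from .connectivity import BinaryGraph, ConnectivityMatrix, SignedWeightedGraph, threshold_density

__all__ = [
    "modularity",
    "modularity_score",
    "global_efficiency",
    "local_efficiency",
    "participation",
    "CanonicalAssignment",
    "consistent_nodes",
    "module_connectivity",
    "compute_metric_tables",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(0.02, 0.1001, 0.01), 10)
)


def _adjacency(G: "BinaryGraph | np.ndarray") -> np.ndarray:
    a = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    return np.asarray(a, dtype=float)


def modularity(G: "BinaryGraph | np.ndarray", partition: "Partition | np.ndarray", gamma: float = 1.0) -> float:
    """Newman modularity Q = (1/2E) sum_ij [A_ij - gamma k_i k_j / 2E] delta."""
    A = _adjacency(G)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if A.sum() <= 0:
        raise ValueError("graph has no edges")
    return weighted_modularity(A, labels, gamma)


def modularity_score(
    G: "BinaryGraph | np.ndarray",
    gamma: float = 1.25,
    runs: int = 500,
    seed: "int | None" = None,
) -> float:
    """Subject-level modularity score: mean Q over ``runs`` independent
    Louvain + fine-tune repetitions at resolution ``gamma``."""
    A = _adjacency(G)
    parts = _community.ensemble_partitions(A, gamma, runs, seed)
    return float(np.mean([weighted_modularity(A, p.labels, gamma) for p in parts]))


def global_efficiency(G: "BinaryGraph | np.ndarray") -> float:
    """Mean inverse shortest-path length over all ordered node pairs;
    disconnected pairs contribute 0."""
    A = _adjacency(G)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    L = shortest_path(A, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(G: "BinaryGraph | np.ndarray") -> np.ndarray:
    """Per-node local efficiency: global efficiency of the sub-graph induced
    by each node's neighbors (the node itself excluded). Nodes with fewer
    than 2 neighbors score 0."""
    A = _adjacency(G)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        L = shortest_path(sub, method="D", unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / L
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        out[i] = inv.sum() / (nbrs.size * (nbrs.size - 1))
    return out


def participation(
    G: "BinaryGraph | np.ndarray", labels: "Partition | np.ndarray"
) -> np.ndarray:
    """Participation coefficient P(i) = 1 - sum_m (k_i(m)/k_i)^2 from module
    labels covering every node; degree-0 nodes score 0."""
    A = _adjacency(G)
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    if lab.shape[0] != A.shape[0]:
        raise ValueError("labels do not cover every node")
    if np.any(lab < 0):
        bad = np.flatnonzero((lab < 0) & (A.sum(axis=1) > 0))
        if bad.size:
            raise ValueError(f"unlabeled node(s) with edges: {bad[:5].tolist()}")
    k = A.sum(axis=1)
    n_mod = int(lab.max()) + 1
    onehot = np.zeros((A.shape[0], n_mod))
    onehot[np.arange(A.shape[0]), lab] = 1.0
    k_im = A @ onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = k_im / k[:, None]
    p = 1.0 - np.nansum(frac**2, axis=1)
    p[k == 0] = 0.0
    return p


@dataclass(frozen=True)
class CanonicalAssignment:
    """Node -> module assignment shared across the four group-session
    partitions.

    ``matched_labels`` maps every cell's partition into the reference label
    space (first group, first session); ``consistent`` flags nodes whose
    matched label agrees across all cells; ``labels`` holds the shared label
    where consistent and -1 elsewhere.
    """

    labels: np.ndarray
    consistent: np.ndarray
    matched_labels: "dict[str, np.ndarray]"
    reference_cell: str

    @property
    def modules(self) -> np.ndarray:
        return np.unique(self.labels[self.consistent])

    def consistent_count(self, module: int) -> int:
        return int(np.sum(self.consistent & (self.labels == module)))


def _match_to_reference(ref: np.ndarray, other: np.ndarray, offset: int) -> np.ndarray:
    """Map ``other``'s module labels onto ``ref``'s via maximum-overlap
    one-to-one assignment on the confusion matrix; unmatched modules get
    fresh labels starting at ``offset`` so their nodes can never count as
    consistent but still define modules for neighbor counting."""
    n_ref = int(ref.max()) + 1
    n_oth = int(other.max()) + 1
    confusion = np.zeros((n_oth, n_ref))
    np.add.at(confusion, (other, ref), 1)
    rows, cols = linear_sum_assignment(-confusion)
    mapping = np.full(n_oth, -1)
    for r, c in zip(rows, cols):
        if confusion[r, c] > 0:
            mapping[r] = c
    nxt = offset
    for m in range(n_oth):
        if mapping[m] < 0:
            mapping[m] = nxt
            nxt += 1
    return mapping[other]


def consistent_nodes(partitions: "dict[str, Partition]") -> CanonicalAssignment:
    """Canonical assignment from the group-session partitions (typically 4:
    2 groups x 2 sessions). The first entry is the reference; the others are
    label-matched to it by optimal assignment; a node is consistent iff all
    matched labels agree."""
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    cells = list(partitions)
    ref_cell = cells[0]
    ref = partitions[ref_cell].labels
    n = ref.shape[0]
    matched: dict[str, np.ndarray] = {ref_cell: ref.copy()}
    offset = int(ref.max()) + 1
    for cell in cells[1:]:
        lab = partitions[cell].labels
        if lab.shape[0] != n:
            raise ValueError("partitions cover different node sets")
        matched[cell] = _match_to_reference(ref, lab, offset)
        offset = max(offset, int(matched[cell].max()) + 1)
    stacked = np.stack([matched[c] for c in cells])
    consistent = np.all(stacked == stacked[0], axis=0) & (stacked[0] < int(ref.max()) + 1)
    labels = np.where(consistent, stacked[0], -1)
    return CanonicalAssignment(
        labels=labels,
        consistent=consistent,
        matched_labels=matched,
        reference_cell=ref_cell,
    )


def module_connectivity(
    W: "SignedWeightedGraph | np.ndarray", assignment: CanonicalAssignment
) -> pd.DataFrame:
    """Mean FDR-surviving connectivity within and between modules, over
    consistent nodes only: the sum of surviving weights divided by the
    number of possible connections. Within values for modules with < 2
    consistent nodes are reported as missing."""
    weights = W.weights if isinstance(W, SignedWeightedGraph) else np.asarray(W)
    mods = assignment.modules
    rows = []
    for a_idx, m in enumerate(mods):
        nodes_m = np.flatnonzero(assignment.consistent & (assignment.labels == m))
        n_m = nodes_m.size
        if n_m >= 2:
            block = weights[np.ix_(nodes_m, nodes_m)]
            within = float(np.triu(block, 1).sum() / (n_m * (n_m - 1) / 2))
        else:
            within = np.nan
        rows.append(dict(module_a=int(m), module_b=int(m), kind="within", value=within))
        for m2 in mods[a_idx + 1 :]:
            nodes_m2 = np.flatnonzero(assignment.consistent & (assignment.labels == m2))
            denom = n_m * nodes_m2.size
            value = (
                float(weights[np.ix_(nodes_m, nodes_m2)].sum() / denom)
                if denom
                else np.nan
            )
            rows.append(
                dict(module_a=int(m), module_b=int(m2), kind="between", value=value)
            )
    return pd.DataFrame(rows)


def compute_metric_tables(
    connectivity: "dict[tuple[str, int], ConnectivityMatrix]",
    groups: "dict[str, str]",
    assignment: "CanonicalAssignment | None" = None,
    thresholds: "tuple[float, ...]" = DEFAULT_THRESHOLDS,
    gamma: float = 1.25,
    runs: int = 100,
    seed: "int | None" = None,
    fdr_graphs: "dict[tuple[str, int], dict[str, SignedWeightedGraph]] | None" = None,
) -> "tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]":
    """Per-subject x session x threshold brain-wide metrics, plus the
    across-threshold mean row (density = 'mean'); when a canonical
    assignment is given, per-module participation / local-efficiency tables
    and (when FDR graphs are given) within/between-module connectivity.

    Q uses the Louvain-mean modularity score with ``runs`` repetitions per
    graph; Eglob / Eloc are exact. Seeds are derived per (subject, session,
    threshold) from the master seed.
    """
    ss = np.random.SeedSequence(seed)
    keys = sorted(connectivity)
    child = ss.spawn(len(keys))
    rows, mod_rows, conn_rows = [], [], []
    for (key, cseed) in zip(keys, child):
        sid, session = key
        C = connectivity[key]
        tseeds = cseed.spawn(len(thresholds))
        per_thresh = []
        for d, tseed in zip(thresholds, tseeds):
            G = threshold_density(C, float(d))
            q = modularity_score(G, gamma=gamma, runs=runs, seed=tseed)
            eg = global_efficiency(G)
            eloc = local_efficiency(G)
            rows.append(
                dict(
                    subject_id=sid,
                    group=groups[sid],
                    session=session,
                    density=float(d),
                    Q=q,
                    Eglob=eg,
                    Eloc_mean=float(eloc.mean()),
                )
            )
            per_thresh.append(rows[-1])
            if assignment is not None:
                cell = f"{groups[sid]}|{session}"
                cell_labels = assignment.matched_labels.get(
                    cell, assignment.matched_labels[assignment.reference_cell]
                )
                p = participation(G, cell_labels)
                for m in assignment.modules:
                    nodes_m = np.flatnonzero(
                        assignment.consistent & (assignment.labels == m)
                    )
                    mod_rows.append(
                        dict(
                            subject_id=sid,
                            group=groups[sid],
                            session=session,
                            density=float(d),
                            module=int(m),
                            participation=float(p[nodes_m].mean()),
                            local_efficiency=float(eloc[nodes_m].mean()),
                        )
                    )
        mean_row = dict(
            subject_id=sid,
            group=groups[sid],
            session=session,
            density="mean",
            Q=float(np.mean([r["Q"] for r in per_thresh])),
            Eglob=float(np.mean([r["Eglob"] for r in per_thresh])),
            Eloc_mean=float(np.mean([r["Eloc_mean"] for r in per_thresh])),
        )
        rows.append(mean_row)
        if assignment is not None and fdr_graphs is not None and key in fdr_graphs:
            for sign, graph in fdr_graphs[key].items():
                tab = module_connectivity(graph, assignment)
                tab.insert(0, "subject_id", sid)
                tab.insert(1, "group", groups[sid])
                tab.insert(2, "session", session)
                tab.insert(3, "sign", sign)
                conn_rows.append(tab)
    metric_table = pd.DataFrame(rows)
    module_table = None
    if mod_rows:
        module_table = pd.DataFrame(mod_rows)
        means = (
            module_table.groupby(["subject_id", "group", "session", "module"], as_index=False)[
                ["participation", "local_efficiency"]
            ]
            .mean()
            .assign(density="mean")
        )
        module_table = pd.concat([module_table, means], ignore_index=True)
    conn_table = pd.concat(conn_rows, ignore_index=True) if conn_rows else None
    return metric_table, module_table, conn_table
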