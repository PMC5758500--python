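"""Louvain community detection with consensus clustering.

Implements weighted Louvain with a resolution parameter, iterative community
fine-tuning, best-of-R partition selection, agreement matrices, iterated
consensus clustering at the subject and group level, and the (gamma, tau)
grid sweep used to pick the resolution and agreement-threshold parameters.

The modularity objective throughout is the configuration-model form

    Q = (1/2m) * sum_ij [W_ij - gamma * s_i s_j / 2m] * delta(m_i, m_j)

with node strengths s_i in place of degrees for weighted graphs; the sum
runs over ordered pairs including i = j (W_ii = 0 on input graphs, but the
null term s_i^2/2m is counted), the standard Newman convention.

Seed management: every stochastic entry point takes a single seed (or an
``np.random.Generator``); internal repetitions draw child seeds from a
``SeedSequence`` spawned from it, so results are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Partition",
    "ConsensusParams",
    "weighted_modularity",
    "louvain",
    "fine_tune",
    "best_partition",
    "agreement",
    "consensus_partition",
    "matrix_consensus",
    "subject_consensus",
    "group_consensus",
    "sweep_parameters",
    "SweepResult",
]


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules contiguously in order of first occurrence."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {int(old): new for new, old in enumerate(order)}
    return np.array([mapping[int(x)] for x in labels], dtype=np.int64)


@dataclass(frozen=True)
class Partition:
    """Node -> module labeling, stored in canonical (first-occurrence) form."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", canonical_labels(self.labels))
        self.labels.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def module_count(self) -> int:
        return int(self.labels.max()) + 1 if self.n_nodes else 0

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and np.array_equal(
            self.labels, other.labels
        )

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())


@dataclass(frozen=True)
class ConsensusParams:
    """Knobs of the consensus procedure: Louvain resolution ``gamma``,
    agreement threshold ``tau``, Louvain repetitions ``runs`` per stage,
    and the consensus iteration cap."""

    gamma: float = 1.25
    tau: float = 0.5
    runs: int = 500
    max_consensus_iterations: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.max_consensus_iterations < 1:
            raise ValueError("max_consensus_iterations must be >= 1")


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("weight matrix must be non-negative")
    if W.sum() <= 0:
        raise ValueError("weight matrix has no edges")
    return W


def weighted_modularity(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Configuration-null modularity of a labeling on a non-negative
    symmetric weight matrix (self-pairs included in the null term)."""
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    two_m = W.sum()
    if two_m <= 0:
        raise ValueError("graph has no edges")
    strength = W.sum(axis=1)
    n_mod = int(labels.max()) + 1
    s_c = np.bincount(labels, weights=strength, minlength=n_mod)
    # internal weight per community over ordered pairs
    onehot = np.zeros((len(labels), n_mod))
    onehot[np.arange(len(labels)), labels] = 1.0
    w_cc = np.einsum("ic,ij,jc->c", onehot, W, onehot)
    return float(w_cc.sum() / two_m - gamma * np.sum((s_c / two_m) ** 2))


# ---------------------------------------------------------------------------
# Louvain core

def _move_nodes(
    W: np.ndarray,
    labels: np.ndarray,
    gamma: float,
    order: np.ndarray,
    max_sweeps: int = 100,
) -> bool:
    """Greedy local-moving phase (in place). Each node moves to the community
    with the largest positive modularity gain; repeats full sweeps until no
    node moves. Returns True if any move was made."""
    two_m = W.sum()
    strength = W.sum(axis=1)
    self_w = np.diag(W).copy()
    n_slots = int(labels.max()) + 1
    comm_strength = np.bincount(labels, weights=strength, minlength=n_slots)
    improved = False
    for _ in range(max_sweeps):
        moved = False
        for i in order:
            a = labels[i]
            w_ic = np.bincount(labels, weights=W[i], minlength=n_slots)
            w_ic[a] -= self_w[i]
            s_i = strength[i]
            s_excl = comm_strength.copy()
            s_excl[a] -= s_i
            gain = w_ic - gamma * s_i * s_excl / two_m
            b = int(np.argmax(gain))
            if gain[b] - gain[a] > 1e-12 and b != a:
                labels[i] = b
                comm_strength[a] -= s_i
                comm_strength[b] += s_i
                moved = True
                improved = True
        if not moved:
            break
    return improved


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Collapse communities into super-nodes; the diagonal of the result
    holds each community's internal weight over ordered pairs, so total
    weight and strengths are preserved."""
    n_mod = int(labels.max()) + 1
    onehot = np.zeros((len(labels), n_mod))
    onehot[np.arange(len(labels)), labels] = 1.0
    return onehot.T @ W @ onehot


def _louvain_labels(
    W: np.ndarray, gamma: float, rng: np.random.Generator, init: np.ndarray | None = None
) -> np.ndarray:
    """Full multi-level Louvain; returns node labels.

    ``init`` seeds the first local-moving phase (singletons if None). Each
    level runs greedy local moving then aggregates communities into
    super-nodes; modularity strictly increases across improved levels, so
    the loop terminates.
    """
    n = W.shape[0]
    working = np.arange(n) if init is None else canonical_labels(init)
    working = working.copy()
    improved = _move_nodes(W, working, gamma, rng.permutation(n))
    node_to_comm = canonical_labels(working)
    if not improved and init is None:
        return node_to_comm
    graph = _aggregate(W, node_to_comm)
    for _ in range(10_000):  # safety bound; Q strictly increases per level
        m = graph.shape[0]
        working = np.arange(m)
        improved = _move_nodes(graph, working, gamma, rng.permutation(m))
        if not improved:
            return node_to_comm
        working = canonical_labels(working)
        node_to_comm = working[node_to_comm]
        graph = _aggregate(graph, working)
    return node_to_comm


def louvain(
    W: np.ndarray,
    gamma: float = 1.0,
    seed: "int | np.random.Generator | None" = None,
) -> Partition:
    """Two-phase Louvain maximization of resolution-``gamma`` modularity on a
    non-negative symmetric weight matrix. Node visit order is shuffled by
    ``seed``; returns a canonical-labeled :class:`Partition`."""
    W = _check_weights(W)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return Partition(_louvain_labels(W, gamma, rng))


def fine_tune(W: np.ndarray, partition: Partition, gamma: float = 1.0) -> Partition:
    """Iterative community fine-tuning: deterministic single-node reassignment
    sweeps followed by re-running Louvain initialized from the result, until a
    full sweep yields no modularity gain. Output Q is never below input Q."""
    W = _check_weights(W)
    if partition.n_nodes != W.shape[0]:
        raise ValueError("partition does not match graph size")
    labels = partition.labels.copy()
    rng = np.random.default_rng(0)  # deterministic by contract
    order = np.arange(W.shape[0])
    for _ in range(100):
        working = labels.copy()
        moved = _move_nodes(W, working, gamma, order, max_sweeps=1)
        if not moved:
            break
        labels = _louvain_labels(W, gamma, rng, init=canonical_labels(working))
    return Partition(labels)


def _spawn_seeds(
    seed: "int | np.random.SeedSequence | None", n: int
) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def best_partition(
    W: np.ndarray,
    gamma: float = 1.0,
    runs: int = 100,
    seed: "int | None" = None,
) -> tuple[Partition, float]:
    """Best of ``runs`` Louvain + fine-tune repetitions (distinct derived
    seeds); ties on Q broken by the lowest canonical label sequence."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    W = _check_weights(W)
    best: tuple[float, tuple, Partition] | None = None
    for rng in _spawn_seeds(seed, runs):
        part = fine_tune(W, louvain(W, gamma, rng), gamma)
        q = weighted_modularity(W, part.labels, gamma)
        key = (-q, tuple(part.labels))
        if best is None or key < best[:2]:
            best = (-q, tuple(part.labels), part)
    assert best is not None
    return best[2], -best[0]


def ensemble_partitions(
    W: np.ndarray, gamma: float, runs: int, seed: "int | None"
) -> list[Partition]:
    """``runs`` independent Louvain + fine-tune partitions (derived seeds)."""
    W = _check_weights(W)
    return [fine_tune(W, louvain(W, gamma, rng), gamma) for rng in _spawn_seeds(seed, runs)]


# ---------------------------------------------------------------------------
# consensus clustering

def agreement(partitions: "list[Partition]") -> np.ndarray:
    """Co-assignment frequency matrix: entry (i, j) is the fraction of
    partitions assigning nodes i and j to the same module."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    n = partitions[0].n_nodes
    acc = np.zeros((n, n))
    for p in partitions:
        if p.n_nodes != n:
            raise ValueError("partitions cover different node sets")
        same = p.labels[:, None] == p.labels[None, :]
        acc += same
    return acc / len(partitions)


def consensus_partition(
    partitions: "list[Partition]", params: ConsensusParams
) -> Partition:
    """Iterated consensus: build the agreement matrix, zero entries below
    ``tau``, re-partition it with ``runs`` Louvain + fine-tune repetitions;
    repeat until all runs of an iteration agree.

    Surviving agreement entries keep their fractional values. Raises if no
    off-diagonal entry reaches ``tau`` or the iteration cap is hit.
    """
    current = list(partitions)
    seeds = np.random.SeedSequence(params.seed).spawn(params.max_consensus_iterations)
    for it in range(params.max_consensus_iterations):
        if len(set(current)) == 1 and it > 0:
            return current[0]
        A = agreement(current)
        A = np.where(A >= params.tau, A, 0.0)
        np.fill_diagonal(A, 0.0)
        if A.sum() == 0:
            raise ValueError(
                f"no pairwise agreement reaches tau={params.tau}; "
                "lower tau or increase runs"
            )
        rngs = [np.random.default_rng(c) for c in seeds[it].spawn(params.runs)]
        current = [fine_tune(A, louvain(A, params.gamma, rng), params.gamma) for rng in rngs]
        if len(set(current)) == 1:
            return current[0]
    raise RuntimeError(
        f"consensus did not converge in {params.max_consensus_iterations} "
        f"iterations; consider a different tau"
    )


def matrix_consensus(W: np.ndarray, params: ConsensusParams) -> Partition:
    """Consensus partition of a single weight matrix: ``runs`` Louvain +
    fine-tune partitions of W, then iterated consensus on the ensemble."""
    parts = ensemble_partitions(W, params.gamma, params.runs, params.seed)
    if len(set(parts)) == 1:
        return parts[0]
    sub = replace(params, seed=None if params.seed is None else params.seed + 1)
    return consensus_partition(parts, sub)


def positive_weights(values: np.ndarray) -> np.ndarray:
    """Positive part of a signed connectivity matrix, zero diagonal."""
    W = np.where(np.asarray(values, dtype=float) > 0, values, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def subject_consensus(C, params: ConsensusParams) -> Partition:
    """Threshold-independent subject-level consensus partition: Louvain on
    the positive Fisher-z weights, repeated and consensus-clustered."""
    return matrix_consensus(positive_weights(C.values), params)


def group_consensus(
    subject_partitions: "list[Partition]", params: ConsensusParams
) -> Partition:
    """Group-level consensus over the subjects' consensus partitions."""
    if len(subject_partitions) < 2:
        raise ValueError("need at least two subjects for a group consensus")
    return consensus_partition(subject_partitions, params)


@dataclass(frozen=True)
class SweepResult:
    gamma: float
    tau: float
    mean_q: float
    grid: "list[dict]"
    partitions: "dict[str, Partition]"


def sweep_parameters(
    group_matrices: "dict[str, np.ndarray]",
    gamma_range: "np.ndarray | list[float]" = None,
    tau_range: "np.ndarray | list[float]" = None,
    params: ConsensusParams | None = None,
) -> SweepResult:
    """Grid search over (gamma, tau): for each grid point, derive each
    group-session cell's consensus partition from its mean positive-weight
    matrix and score it by weighted modularity on that same matrix; return
    the grid and the argmax of the mean Q (ties -> smallest gamma, then tau).

    Default ranges are gamma 1.0-1.5 and tau 0.2-0.5 in steps of 0.05.
    Cells whose consensus fails at a grid point mark that point failed and
    exclude it from the argmax.
    """
    if gamma_range is None:
        gamma_range = np.round(np.arange(1.0, 1.5001, 0.05), 10)
    if tau_range is None:
        tau_range = np.round(np.arange(0.2, 0.5001, 0.05), 10)
    if params is None:
        params = ConsensusParams()
    if len(group_matrices) == 0:
        raise ValueError("need at least one group-session matrix")
    grid: list[dict] = []
    best: tuple[float, float, float] | None = None
    best_parts: dict[str, Partition] = {}
    for g in gamma_range:
        for t in tau_range:
            point = replace(params, gamma=float(g), tau=float(t))
            qs, parts, ok = [], {}, True
            for cell, W in group_matrices.items():
                try:
                    part = matrix_consensus(W, point)
                except (ValueError, RuntimeError):
                    ok = False
                    break
                parts[cell] = part
                qs.append(weighted_modularity(W, part.labels, float(g)))
            mean_q = float(np.mean(qs)) if ok else np.nan
            grid.append(
                dict(gamma=float(g), tau=float(t), mean_q=mean_q, converged=ok)
            )
            if ok and (best is None or mean_q > best[0] + 1e-15):
                best = (mean_q, float(g), float(t))
                best_parts = parts
    if best is None:
        raise RuntimeError("every grid point failed to converge")
    return SweepResult(
        gamma=best[1], tau=best[2], mean_q=best[0], grid=grid, partitions=best_parts
    )
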