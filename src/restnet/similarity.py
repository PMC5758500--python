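"""Partition-similarity analysis via normalized mutual information.

NMI here is 2*I(X;Y)/(H(X)+H(Y)) (arithmetic-mean normalization, natural
logs) computed from the module contingency table. Three permutation tests
compare community structure across subjects:

* between-group: is the average cross-group pairwise NMI lower than under
  random group assignment (one-sided, per the 5th-percentile rule, with a
  two-sided p also reported)?
* within-group: is each group's average within-group pairwise NMI higher or
  lower than under random assignment (two-sided)?
* within-subject over time: does the session-1 vs session-2 NMI differ
  between groups (two-sided difference of group means)?

All tests precompute the observed pairwise-NMI matrix once and reuse it
across label permutations, and report finite-sample-corrected p-values
p = (1 + #{null at least as extreme}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import Partition

__all__ = [
    "nmi",
    "NmiResult",
    "PermTestResult",
    "between_group_test",
    "within_group_similarity_test",
    "within_subject_over_time_test",
]


def nmi(p1: "Partition | np.ndarray", p2: "Partition | np.ndarray") -> float:
    """Normalized mutual information between two labelings of one node set.

    Returns 1 when both partitions are single-module (zero entropy on both
    sides) and 0 when exactly one is.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions cover different node sets")
    return _nmi_labels(a, b)


def _nmi_labels(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    cont = np.zeros((na, nb))
    np.add.at(cont, (a, b), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pi > 0
    h_a = float(-np.sum(pi[nz] * np.log(pi[nz])))
    nz = pj > 0
    h_b = float(-np.sum(pj[nz] * np.log(pj[nz])))
    if h_a + h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / np.outer(pi, pj)[mask])))
    return 2.0 * mi / (h_a + h_b)


@dataclass(frozen=True)
class NmiResult:
    """Observed mean NMI, its permutation null, and p-values."""

    observed: float
    null_distribution: np.ndarray
    p_value: float
    p_two_sided: float
    significant_low: bool  # observed below the null's 5th percentile
    n_permutations: int
    per_threshold: "dict[float, float]" = field(default_factory=dict)


@dataclass(frozen=True)
class PermTestResult:
    """Observed statistic, its permutation null, and p-values."""

    statistic: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    seed: "int | None" = None


def _as_label_array(partitions) -> np.ndarray:
    """Stack per-subject partitions into (n_subjects, n_thresholds, n_nodes).

    Accepts, per subject: a Partition, a 1-D label array (treated as a
    single threshold), or a sequence of either (one per threshold).
    """
    stacked = []
    for entry in partitions:
        if isinstance(entry, Partition):
            stacked.append(entry.labels[None, :])
        elif isinstance(entry, np.ndarray) and entry.ndim == 1:
            stacked.append(entry[None, :])
        else:
            stacked.append(
                np.stack(
                    [e.labels if isinstance(e, Partition) else np.asarray(e) for e in entry]
                )
            )
    arr = np.stack(stacked)
    return arr


def _pairwise_nmi(labels: np.ndarray) -> np.ndarray:
    """(n_thresholds, n_subjects, n_subjects) pairwise NMI matrices."""
    n_sub, n_thr, _ = labels.shape
    out = np.zeros((n_thr, n_sub, n_sub))
    for t in range(n_thr):
        for i in range(n_sub):
            out[t, i, i] = 1.0
            for j in range(i + 1, n_sub):
                v = _nmi_labels(labels[i, t], labels[j, t])
                out[t, i, j] = out[t, j, i] = v
    return out


def _cross_mean(nmi_mat: np.ndarray, is_g1: np.ndarray) -> float:
    """Mean pairwise NMI over cross-group pairs, averaged over thresholds."""
    mask = np.outer(is_g1, ~is_g1)
    return float(nmi_mat[:, mask].mean())


def _within_mean(nmi_mat: np.ndarray, members: np.ndarray) -> float:
    idx = np.flatnonzero(members)
    iu, ju = np.triu_indices(idx.size, k=1)
    return float(nmi_mat[:, idx[iu], idx[ju]].mean())


def _p_low(null: np.ndarray, obs: float, n_perm: int) -> float:
    return (1 + int(np.sum(null <= obs))) / (n_perm + 1)


def _p_two(null: np.ndarray, obs: float, n_perm: int) -> float:
    lo = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
    hi = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    return min(1.0, 2.0 * min(lo, hi))


def between_group_test(
    partitions_group1,
    partitions_group2,
    n_perm: int = 5000,
    seed: "int | None" = None,
) -> NmiResult:
    """Between-group partition-similarity test.

    Each subject contributes one partition per density threshold (the
    highest-modularity partition). The observed statistic is the mean
    pairwise NMI over all cross-group subject pairs (per threshold, then
    averaged); the null shuffles group membership keeping group sizes.
    """
    if len(partitions_group1) < 2 or len(partitions_group2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    l1 = _as_label_array(partitions_group1)
    l2 = _as_label_array(partitions_group2)
    labels = np.concatenate([l1, l2])
    n1 = l1.shape[0]
    n = labels.shape[0]
    nmi_mat = _pairwise_nmi(labels)
    is_g1 = np.zeros(n, dtype=bool)
    is_g1[:n1] = True
    observed = _cross_mean(nmi_mat, is_g1)
    per_thr = {
        t: float(nmi_mat[t][np.outer(is_g1, ~is_g1)].mean())
        for t in range(nmi_mat.shape[0])
    }
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        null[b] = _cross_mean(nmi_mat, mask)
    return NmiResult(
        observed=observed,
        null_distribution=null,
        p_value=_p_low(null, observed, n_perm),
        p_two_sided=_p_two(null, observed, n_perm),
        significant_low=observed < np.percentile(null, 5),
        n_permutations=n_perm,
        per_threshold=per_thr,
    )


def within_group_similarity_test(
    partitions_group1,
    partitions_group2,
    n_perm: int = 5000,
    seed: "int | None" = None,
) -> "dict[str, NmiResult]":
    """Within-group partition similarity for each group against the
    group-shuffled null (two-sided: a group may be more or less internally
    similar than chance)."""
    if len(partitions_group1) < 2 or len(partitions_group2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    l1 = _as_label_array(partitions_group1)
    l2 = _as_label_array(partitions_group2)
    labels = np.concatenate([l1, l2])
    n1, n = l1.shape[0], l1.shape[0] + l2.shape[0]
    nmi_mat = _pairwise_nmi(labels)
    is_g1 = np.zeros(n, dtype=bool)
    is_g1[:n1] = True
    rng = np.random.default_rng(seed)
    results: dict[str, NmiResult] = {}
    nulls = {1: np.empty(n_perm), 2: np.empty(n_perm)}
    for b in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        nulls[1][b] = _within_mean(nmi_mat, mask)
        nulls[2][b] = _within_mean(nmi_mat, ~mask)
    for key, members in (("group1", is_g1), ("group2", ~is_g1)):
        g = 1 if key == "group1" else 2
        obs = _within_mean(nmi_mat, members)
        per_thr = {}
        idx = np.flatnonzero(members)
        iu, ju = np.triu_indices(idx.size, k=1)
        for t in range(nmi_mat.shape[0]):
            per_thr[t] = float(nmi_mat[t, idx[iu], idx[ju]].mean())
        results[key] = NmiResult(
            observed=obs,
            null_distribution=nulls[g],
            p_value=_p_low(nulls[g], obs, n_perm),
            p_two_sided=_p_two(nulls[g], obs, n_perm),
            significant_low=obs < np.percentile(nulls[g], 5),
            n_permutations=n_perm,
            per_threshold=per_thr,
        )
    return results


def within_subject_over_time_test(
    partitions_t1,
    partitions_t2,
    group_labels,
    n_perm: int = 5000,
    seed: "int | None" = None,
) -> "tuple[PermTestResult, np.ndarray]":
    """Between-group difference in within-subject partition stability.

    ``partitions_t1`` / ``partitions_t2`` are per-subject (aligned) session
    partitions; the per-subject statistic is NMI(t1, t2) averaged over
    thresholds, and the test statistic is the group-1 minus group-2 mean,
    against a group-label-shuffling null (two-sided). Returns the test
    result and the per-subject NMI values.
    """
    l1 = _as_label_array(partitions_t1)
    l2 = _as_label_array(partitions_t2)
    if l1.shape != l2.shape:
        raise ValueError("session partition sets do not match")
    groups = np.asarray(group_labels)
    if groups.shape[0] != l1.shape[0]:
        raise ValueError("group labels do not match subjects")
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    per_subject = np.array(
        [
            np.mean([_nmi_labels(l1[i, t], l2[i, t]) for t in range(l1.shape[1])])
            for i in range(l1.shape[0])
        ]
    )
    g1 = groups == uniq[0]
    observed = float(per_subject[g1].mean() - per_subject[~g1].mean())
    rng = np.random.default_rng(seed)
    n1 = int(g1.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(per_subject.shape[0])
        null[b] = per_subject[perm[:n1]].mean() - per_subject[perm[n1:]].mean()
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (n_perm + 1)
    return (
        PermTestResult(
            statistic=observed,
            null_distribution=null,
            p_value=p,
            n_permutations=n_perm,
            seed=seed,
        ),
        per_subject,
    )
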