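"""Independent brute-force oracles for the test suite.

Deliberately naive implementations (double loops, hand BFS, explicit
sums of squares, exhaustive enumeration) kept separate from the package's
code paths so they can serve as ground truth.
"""

from collections import deque

import numpy as np


def modularity_pairsum(A, labels, gamma=1.0):
    """Term-by-term double loop over ordered pairs, including i = j."""
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    k = A.sum(axis=1)
    two_e = A.sum()
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_e
    return q / two_e


def modularity_percommunity(A, labels, gamma=1.0):
    """Closed-form per-community sum: sum_c (e_c/E - gamma (d_c/2E)^2)."""
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    two_e = A.sum()
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        e_c = A[np.ix_(members, members)].sum()  # ordered pairs
        d_c = A[members].sum()
        q += e_c / two_e - gamma * (d_c / two_e) ** 2
    return q


def bfs_distances(A, source):
    """Hop counts from source; np.inf for unreachable nodes."""
    n = A.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(A[u]):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def global_efficiency_bfs(A):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        dist = bfs_distances(A, i)
        for j in range(n):
            if j != i and np.isfinite(dist[j]):
                total += 1.0 / dist[j]
    return total / (n * (n - 1))


def local_efficiency_bfs(A):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        total = 0.0
        for a in range(nbrs.size):
            dist = bfs_distances(sub, a)
            for b in range(nbrs.size):
                if b != a and np.isfinite(dist[b]):
                    total += 1.0 / dist[b]
        out[i] = total / (nbrs.size * (nbrs.size - 1))
    return out


def participation_counts(A, labels):
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k_i = A[i].sum()
        if k_i == 0:
            continue
        acc = 0.0
        for m in np.unique(labels):
            k_im = A[i, labels == m].sum()
            acc += (k_im / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def bh_stepup(pvals, q):
    """Benjamini-Hochberg: largest i with p_(i) <= i q / m; reject all
    hypotheses with p below that cutoff. Returns a boolean mask."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def icc_hand_anova(x):
    """ICC(A,k) from explicit sum-of-squares formulas."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_r = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_c = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_t = ((x - grand) ** 2).sum()
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = (ss_t - ss_r - ss_c) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)


def nmi_entropy(a, b):
    """NMI via explicit entropy sums from the contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    h_a = 0.0
    for lab in np.unique(a):
        p = np.mean(a == lab)
        h_a -= p * np.log(p)
    h_b = 0.0
    for lab in np.unique(b):
        p = np.mean(b == lab)
        h_b -= p * np.log(p)
    mi = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            pij = np.mean((a == la) & (b == lb))
            if pij > 0:
                mi += pij * np.log(pij / (np.mean(a == la) * np.mean(b == lb)))
    if h_a + h_b == 0:
        return 1.0
    if h_a == 0 or h_b == 0:
        return 0.0
    return 2 * mi / (h_a + h_b)


def set_partitions(n):
    """All set partitions of range(n) as label arrays (restricted-growth
    strings), Bell(n) of them."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def exhaustive_max_modularity(A, gamma=1.0):
    """Exhaustive search over all set partitions (n <= 10ish)."""
    best = -np.inf
    for labels in set_partitions(A.shape[0]):
        q = modularity_percommunity(A, labels, gamma)
        if q > best:
            best = q
    return best
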