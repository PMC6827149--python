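"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than
the package: exact rational arithmetic for the summary statistics,
direct recursion for Stirling numbers, brute-force enumeration for
spanning trees, and tree construction + path-length readback for
additive matrices.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np

_GOOD = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Exact-rational popgen statistics


def exact_hd(counts: list[int]) -> tuple[Fraction, Fraction]:
    """Nei's haplotype diversity and variance as exact rationals."""
    n = sum(counts)
    p = [Fraction(c, n) for c in counts]
    s2 = sum(pi ** 2 for pi in p)
    s3 = sum(pi ** 3 for pi in p)
    hd = Fraction(n, n - 1) * (1 - s2)
    var = Fraction(2, n * (n - 1)) * (
        2 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return hd, var


def exact_pairwise(seqs: list[str]) -> tuple[Fraction, Fraction]:
    """(K, L_effective) under pairwise deletion, exact."""
    n = len(seqs)
    pairs = n * (n - 1) // 2
    total_d = total_l = 0
    for i, j in itertools.combinations(range(n), 2):
        for a, b in zip(seqs[i], seqs[j]):
            if a in _GOOD and b in _GOOD:
                total_l += 1
                if a != b:
                    total_d += 1
    return Fraction(total_d, pairs), Fraction(total_l, pairs)


def exact_complete_deletion(seqs: list[str]) -> list[int]:
    L = len(seqs[0])
    return [c for c in range(L) if all(s[c] in _GOOD for s in seqs)]


def exact_S(seqs: list[str]) -> int:
    cols = exact_complete_deletion(seqs)
    return sum(1 for c in cols if len({s[c] for s in seqs}) > 1)


def exact_tajima_d(seqs: list[str]) -> float:
    """Tajima's D via exact rationals for every term except the final
    square root (complete deletion for both K and S)."""
    n = len(seqs)
    cols = exact_complete_deletion(seqs)
    sub = ["".join(s[c] for c in cols) for s in seqs]
    S = sum(1 for c in range(len(cols)) if len({s[c] for s in sub}) > 1)
    if S == 0:
        return 0.0
    pairs = n * (n - 1) // 2
    k = Fraction(sum(sum(a != b for a, b in zip(sub[i], sub[j]))
                     for i, j in itertools.combinations(range(n), 2)), pairs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    num = k - Fraction(S) / a1
    var = e1 * S + e2 * S * (S - 1)
    return float(num) / math.sqrt(float(var))


# ---------------------------------------------------------------------------
# Stirling numbers / Ewens


@lru_cache(maxsize=None)
def stirling1_unsigned(n: int, k: int) -> int:
    """Direct recursive definition, exact integers."""
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0 or k > n:
        return 0
    return stirling1_unsigned(n - 1, k - 1) \
        + (n - 1) * stirling1_unsigned(n - 1, k)


def exact_ewens_at_least(k_obs: int, theta: Fraction, n: int) -> Fraction:
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    return sum(stirling1_unsigned(n, k) * theta ** k
               for k in range(k_obs, n + 1)) / rising


# ---------------------------------------------------------------------------
# Spanning-tree enumeration


def bruteforce_msn_edges(dist: np.ndarray) -> set[tuple[int, int]]:
    """Edges belonging to at least one minimum spanning tree, found by
    enumerating every spanning tree."""
    n = dist.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best_w = None
    best_sets: list[frozenset] = []
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if not ok:
            continue
        w = sum(dist[i, j] for i, j in combo)
        if best_w is None or w < best_w:
            best_w = w
            best_sets = [frozenset(combo)]
        elif w == best_w:
            best_sets.append(frozenset(combo))
    return set().union(*best_sets)


# ---------------------------------------------------------------------------
# Random additive trees


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (splits, distance matrix, labels): ``splits`` is the set of
    non-trivial bipartitions (canonical smaller side), the matrix holds
    exact leaf-to-leaf path lengths.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # edge list as (frozenset(leaves on child side), length); grow by
    # splitting random edges of a star
    nodes = {0: None}
    # adjacency representation: dict node -> list of (node, length)
    adj: dict[int, list[tuple[int, float]]] = {0: []}
    nxt = [1]

    def add_edge(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def new_node():
        i = nxt[0]
        nxt[0] += 1
        return i

    leaf_ids = {}
    for t in range(3):
        leaf = new_node()
        leaf_ids[leaf] = labels[t]
        add_edge(0, leaf, float(rng.uniform(0.5, 2.0)))
    for t in range(3, n_taxa):
        # pick a random edge, split it with a new internal node
        all_edges = [(a, b, ln) for a in adj for b, ln in adj[a] if a < b]
        a, b, ln = all_edges[rng.integers(len(all_edges))]
        mid = new_node()
        adj[a] = [(x, l) for x, l in adj[a] if x != b]
        adj[b] = [(x, l) for x, l in adj[b] if x != a]
        cut = float(rng.uniform(0.2, 0.8)) * ln
        add_edge(a, mid, cut)
        add_edge(mid, b, ln - cut)
        leaf = new_node()
        leaf_ids[leaf] = labels[t]
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))

    # distances by DFS from every leaf
    import collections
    dmat = np.zeros((n_taxa, n_taxa))
    index = {lbl: i for i, lbl in enumerate(labels)}
    for leaf, lbl in leaf_ids.items():
        dist = {leaf: 0.0}
        dq = collections.deque([leaf])
        while dq:
            u = dq.popleft()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    dq.append(v)
        for other, olbl in leaf_ids.items():
            dmat[index[lbl], index[olbl]] = dist[other]

    # bipartitions: for each internal edge, leaves on one side
    splits = set()
    all_leaves = frozenset(labels)
    for a in adj:
        for b, _ in adj[a]:
            if a < b and a not in leaf_ids and b not in leaf_ids:
                side = set()
                stack = [b]
                seen = {a, b}
                if b in leaf_ids:
                    side.add(leaf_ids[b])
                while stack:
                    u = stack.pop()
                    for v, _ in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                            if v in leaf_ids:
                                side.add(leaf_ids[v])
                side = frozenset(side)
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    splits.add(min(side, other,
                                   key=lambda s: (len(s), tuple(sorted(s)))))
    return splits, dmat, labels
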