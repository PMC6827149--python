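"""Haplotype networks: minimum spanning network and median-joining.

Distances between haplotypes are mutation steps: Hamming distance over
mutually unambiguous columns, with each maximal gap run counted as one
step (an indel is one event regardless of its length).  The minimum
spanning network (MSN) is the union of all minimum spanning trees; the
median-joining (MJ) network augments it with inferred intermediate
(median/Steiner) haplotypes, the site-wise majority consensus of node
triplets, iterated to a fixed point and pruned.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

_GOOD = frozenset("ACGT-")


class HaplotypeInput:
    """Normalized (id, sequence, frequency) triples for network building."""

    def __init__(self, ids: Sequence[str], seqs: Sequence[str],
                 freqs: Sequence[int] | None = None) -> None:
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("haplotype sequences have unequal lengths")
        self.ids = list(ids)
        self.seqs = list(seqs)
        self.freqs = list(freqs) if freqs is not None else [1] * len(seqs)


def pairwise_steps(a: str, b: str) -> int:
    """Mutation-step distance between two aligned sequences.

    Substitutions count one step each over columns where both symbols
    are unambiguous; a maximal run of columns where exactly one of the
    two is gapped counts as a single step.  Columns involving N are
    skipped.
    """
    if len(a) != len(b):
        raise ValueError("length mismatch")
    steps = 0
    in_gap_run = False
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            in_gap_run = False
            continue
        one_gapped = (x == "-") != (y == "-")
        if one_gapped:
            if not in_gap_run:
                steps += 1
                in_gap_run = True
            continue
        in_gap_run = False
        if x != y:
            steps += 1
    return steps


def haplotype_distances(seqs: Sequence[str]) -> np.ndarray:
    """Symmetric integer matrix of mutation-step distances."""
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_steps(seqs[i], seqs[j])
    return d


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _msn_edges(dist: np.ndarray, epsilon: int = 0
               ) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed union of all minimum spanning trees.

    Kruskal over tied weight classes: an edge of weight w is kept iff
    its endpoints are in different components of the graph formed by
    all kept edges of weight < w - epsilon (so with epsilon = 0 this is
    exactly the set of edges belonging to some MST).
    """
    n = dist.shape[0]
    edges = sorted((int(dist[i, j]), i, j)
                   for i in range(n) for j in range(i + 1, n))
    out: list[tuple[int, int, int]] = []
    weights = sorted({w for w, _, _ in edges})
    for w in weights:
        dsu = _DSU(n)
        for wk, a, b in edges:
            if wk < w - epsilon:
                dsu.union(a, b)
        for wk, i, j in edges:
            if wk == w and dsu.find(i) != dsu.find(j):
                out.append((i, j, w))
    return out


def minimum_spanning_network(dist: np.ndarray,
                             ids: Sequence[str] | None = None,
                             epsilon: int = 0) -> nx.Graph:
    """Union of all minimum spanning trees (epsilon-relaxed).

    Deterministic: depends only on the distance matrix and node order.
    """
    n = dist.shape[0]
    if ids is None:
        ids = [f"H{i + 1}" for i in range(n)]
    g = nx.Graph()
    for i in range(n):
        g.add_node(ids[i])
    for i, j, w in _msn_edges(dist, epsilon):
        g.add_edge(ids[i], ids[j], weight=int(w))
    return g


def _sitewise_median(u: str, v: str, w: str) -> str:
    """Site-wise majority consensus; a three-way tie keeps the state of
    the first sequence in the given (deterministic) order."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)
    return "".join(out)


def median_joining(haplotypes: HaplotypeInput, epsilon: int = 0,
                   max_iter: int = 50) -> nx.Graph:
    """Median-joining haplotype network.

    Iterates: (1) build the epsilon-relaxed MSN over current nodes;
    (2) for every triplet connected by at least two MSN edges, form the
    site-wise majority median; (3) add all new medians whose connection
    cost d(m,u)+d(m,v)+d(m,w) is within epsilon of the minimum over
    candidates; (4) repeat to a fixed point (capped at ``max_iter``
    rounds); (5) prune median vectors that are not on any shortest
    connection between observed haplotypes or have degree < 2.
    Observed haplotypes are never pruned.  Ties break lexicographically
    by haplotype id.

    Node attributes: frequency (0 for medians), is_median; edge
    attribute weight = mutation steps.
    """
    ids = list(haplotypes.ids)
    seqs = list(haplotypes.seqs)
    freqs = list(haplotypes.freqs)
    observed = set(ids)
    median_count = 0

    for iteration in range(max_iter):
        dist = haplotype_distances(seqs)
        order = sorted(range(len(ids)), key=lambda k: ids[k])
        msn = {(min(ids[i], ids[j]), max(ids[i], ids[j]))
               for i, j, _ in _msn_edges(dist, epsilon)}
        adj: dict[str, set[str]] = {x: set() for x in ids}
        for a, b in msn:
            adj[a].add(b)
            adj[b].add(a)
        seq_of = dict(zip(ids, seqs))
        known = set(seqs)
        candidates: dict[str, int] = {}
        for ci in order:
            center = ids[ci]
            nbrs = sorted(adj[center])
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    u, v, w = seq_of[center], seq_of[nbrs[x]], seq_of[nbrs[y]]
                    m = _sitewise_median(u, v, w)
                    if m in known:
                        continue
                    cost = (pairwise_steps(m, u) + pairwise_steps(m, v)
                            + pairwise_steps(m, w))
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        best = min(candidates.values())
        added = False
        for m in sorted(candidates):  # deterministic insertion order
            if candidates[m] <= best + epsilon:
                median_count += 1
                ids.append(f"mv{median_count}")
                seqs.append(m)
                freqs.append(0)
                added = True
        if not added:
            break
    else:
        raise RuntimeError(
            f"median-joining did not converge in {max_iter} rounds "
            f"({len(ids) - len(observed)} medians added)")

    g = minimum_spanning_network(haplotype_distances(seqs), ids, epsilon)
    for i, node in enumerate(ids):
        g.nodes[node]["frequency"] = int(freqs[i])
        g.nodes[node]["is_median"] = node not in observed
        g.nodes[node]["sequence"] = seqs[i]
    _prune_medians(g, observed)
    g.graph["epsilon"] = epsilon
    return g


def _prune_medians(g: nx.Graph, observed: set[str]) -> None:
    """Remove medians of degree < 2 or off every shortest observed-pair
    connection, iterating to a fixed point."""
    changed = True
    while changed:
        changed = False
        medians = sorted(n for n in g if n not in observed)
        if not medians:
            return
        obs = sorted(n for n in g if n in observed)
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for m in medians:
            if g.degree(m) < 2:
                g.remove_node(m)
                changed = True
                continue
            on_path = False
            for a in obs:
                if on_path:
                    break
                for b in obs:
                    if a >= b:
                        continue
                    if (m in sp.get(a, {}) and b in sp.get(m, {})
                            and abs(sp[a][m] + sp[m][b] - sp[a][b]) < 1e-9):
                        on_path = True
                        break
            if not on_path:
                g.remove_node(m)
                changed = True


def network_summary(g: nx.Graph,
                    clade_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-clade subgraph statistics.

    For each clade: number of observed nodes, mean degree within the
    full network, and the fraction of the clade's nodes within one edge
    (hop) of the clade's modal (highest-frequency) haplotype — 1.0 for
    a perfect star.
    """
    rows = []
    for clade in sorted(set(clade_of.values())):
        nodes = sorted(n for n, c in clade_of.items() if c == clade
                       and n in g)
        if not nodes:
            continue
        modal = max(nodes,
                    key=lambda n: (g.nodes[n].get("frequency", 0), n))
        near = {modal} | set(g[modal])
        frac = sum(1 for n in nodes if n in near) / len(nodes)
        rows.append({
            "clade": clade,
            "n_nodes": len(nodes),
            "modal_haplotype": modal,
            "mean_degree": float(np.mean([g.degree(n) for n in nodes])),
            "fraction_within_1_step": frac,
        })
    return pd.DataFrame(rows)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; non-scalar node attributes are stringified."""
    h = nx.Graph()
    h.graph.update({k: str(v) for k, v in g.graph.items()})
    for n, attrs in g.nodes(data=True):
        h.add_node(n, **{k: (v if isinstance(v, (int, float, str, bool))
                             else str(v)) for k, v in attrs.items()})
    for a, b, attrs in g.edges(data=True):
        h.add_edge(a, b, **{k: (v if isinstance(v, (int, float, str, bool))
                                else str(v)) for k, v in attrs.items()})
    nx.write_graphml(h, str(path))


def write_dot(g: nx.Graph, path: str | Path) -> None:
    """Minimal DOT export for quick rendering."""
    lines = ["graph haplonet {"]
    for n, attrs in sorted(g.nodes(data=True)):
        shape = "point" if attrs.get("is_median") else "circle"
        lines.append(
            f'  "{n}" [shape={shape}, '
            f'label="{n} ({attrs.get("frequency", 0)})"];')
    for a, b, attrs in sorted(g.edges(data=True)):
        lines.append(f'  "{a}" -- "{b}" [label={attrs.get("weight", 1)}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
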