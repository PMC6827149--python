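"""Distance-based phylogeny: K2P distances, neighbor-joining, bootstrap.

The Kimura 2-parameter model separates transitions from transversions:
with P the proportion of sites differing by a transition and Q by a
transversion (over pairwise-complete columns),

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Trees are built by Saitou & Nei's neighbor-joining with lexicographic
tie-breaking, supported by nonparametric bootstrap over alignment
columns, and rooted on an outgroup's pendant edge.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

_GOOD = frozenset("ACGT")
_PURINES = frozenset("AG")


class SaturatedPairError(ValueError):
    """K2P distance undefined: a logarithm argument is <= 0."""


class K2PDistance(NamedTuple):
    p: float  # transition-differing site proportion
    q: float  # transversion-differing site proportion
    d: float


def k2p_distance(seq_a: str, seq_b: str) -> K2PDistance:
    """Kimura 2-parameter distance over pairwise-complete columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a in _GOOD and b in _GOOD:
            n += 1
            if a != b:
                if ((a in _PURINES) == (b in _PURINES)):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedPairError(
            f"saturated pair: P={p:.4f}, Q={q:.4f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PDistance(p, q, d)


def k2p_matrix(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j]).d
    return d


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class TreeNode:
    """A node of a (possibly unrooted) phylogenetic tree.

    An unrooted tree is stored rooted at an arbitrary internal node
    (the final NJ trifurcation); ``support`` is a bootstrap percentage
    attached to the edge above the node.
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (sum of branch lengths)."""
    dists: dict[tuple[str, str], float] = {}

    def below(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        acc: dict[str, float] = {}
        child_maps = []
        for c in node.children:
            m = {k: v + (c.length or 0.0) for k, v in below(c).items()}
            child_maps.append(m)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        key = (a, b) if a < b else (b, a)
                        dists[key] = da + db
            acc.update(child_maps[i])
        return acc

    below(tree)
    return dists


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized as its smaller side
    (ties by sorted label tuple)."""
    all_leaves = frozenset(tree.leaf_names())
    splits: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dist: np.ndarray,
                     ids: Sequence[str]) -> tuple[TreeNode, bool]:
    """Saitou-Nei neighbor joining.

    Returns the unrooted tree (rooted at the final trifurcation) and a
    flag telling whether any negative branch length was clamped to 0.
    At each step the pair minimizing
    Q(i,j) = (r - 2) d(i,j) - R_i - R_j is joined; ties break on the
    lexicographically smallest (minimum cluster label, then partner).
    """
    r = len(ids)
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (r, r):
        raise ValueError("distance matrix shape mismatch")
    d = dist.astype(float).copy()
    nodes = [TreeNode(name=i) for i in ids]
    labels = [min(n.leaf_names()) for n in nodes]  # tie-break keys
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        delta = (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        vi = clamp(0.5 * d[i, j] + delta)
        vj = clamp(0.5 * d[i, j] - delta)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = vi, vj
        parent = TreeNode(children=[ni, nj])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final three clusters: star resolution in closed form
    (a, b, c) = nodes
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (da + db - dc))
    b.length = clamp(0.5 * (da + dc - db))
    c.length = clamp(0.5 * (db + dc - da))
    return TreeNode(children=[a, b, c]), clamped


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapResult:
    tree: TreeNode
    n_replicates: int
    n_skipped: int


def bootstrap_supports(seqs: Sequence[str], ids: Sequence[str],
                       n_replicates: int = 1000,
                       seed: int | np.random.Generator | None = None
                       ) -> BootstrapResult:
    """Column-resampling bootstrap supports on the K2P + NJ tree.

    Replicates whose distance matrix is degenerate (a saturated or
    incomparable pair) are skipped and counted; supports are
    percentages of the successful replicates containing each split of
    the full-data tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    L = len(seqs[0])
    tree, _ = neighbor_joining(k2p_matrix(seqs), ids)
    target = bipartitions(tree)
    counts = {s: 0 for s in target}
    skipped = 0
    order = np.argsort(np.array(ids))  # seed use independent of input order
    sorted_seqs = [seqs[i] for i in order]
    sorted_ids = [ids[i] for i in order]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = ["".join(s[c] for c in cols) for s in sorted_seqs]
        try:
            rep_tree, _ = neighbor_joining(k2p_matrix(rep), sorted_ids)
        except (SaturatedPairError, ValueError):
            skipped += 1
            continue
        rep_splits = bipartitions(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    ok = n_replicates - skipped
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = frozenset(tree.leaf_names()) - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = 100.0 * counts[canon] / ok if ok else math.nan
    return BootstrapResult(tree, n_replicates, skipped)


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: TreeNode, outgroup_id: str) -> TreeNode:
    """Root the tree at the midpoint of the outgroup's pendant edge.

    The ingroup topology is unchanged; the outgroup becomes the first
    child of the new root.
    """
    # build undirected adjacency over a copy
    nodes: list[TreeNode] = list(tree.walk())
    idx = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float, float | None]]] = {
        i: [] for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            i, j = idx[id(n)], idx[id(c)]
            adj[i].append((j, c.length or 0.0, c.support))
            adj[j].append((i, c.length or 0.0, c.support))
    leaf_idx = None
    for i, n in enumerate(nodes):
        if n.is_leaf and n.name == outgroup_id:
            leaf_idx = i
            break
    if leaf_idx is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf")
    (nbr, length, support) = adj[leaf_idx][0]

    def rebuild(i: int, parent: int) -> TreeNode:
        src = nodes[i]
        node = TreeNode(name=src.name)
        for j, ln, sup in adj[i]:
            if j == parent:
                continue
            child = rebuild(j, i)
            child.length = ln
            child.support = sup
            node.children.append(child)
        return node

    out_child = TreeNode(name=outgroup_id, length=length / 2.0,
                         support=support)
    in_child = rebuild(nbr, leaf_idx)
    in_child.length = length / 2.0
    in_child.support = support
    return TreeNode(children=[out_child, in_child])


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a root with two children into a trifurcation."""
    if len(tree.children) != 2:
        return tree
    a, b = tree.children
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    if b.is_leaf:  # two-leaf tree: nothing to unroot into
        return tree
    merged_length = (a.length or 0.0) + (b.length or 0.0)
    a.length = merged_length
    a.support = a.support if a.support is not None else b.support
    return TreeNode(children=[a, *b.children])


# ---------------------------------------------------------------------------
# Newick IO


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def to_newick(tree: TreeNode) -> str:
    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            inner = ",".join(rec(c) for c in node.children)
            label = ("" if node.support is None
                     else _fmt_len(node.support))
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return rec(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


class NewickParseError(ValueError):
    pass


_TOKEN = re.compile(r"\s*([(),;:]|[^\s(),;:]+)")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; internal node labels become supports when
    numeric, names otherwise.  Malformed input raises
    :class:`NewickParseError` with the offending position."""
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    it = iter(tokens)
    current = [0]

    def peek():
        return tokens[current[0]] if current[0] < len(tokens) else (None, len(text))

    def take():
        t = peek()
        current[0] += 1
        return t

    def parse_node() -> TreeNode:
        tok, at = peek()
        node = TreeNode()
        if tok == "(":
            take()
            node.children.append(parse_node())
            while True:
                tok, at = peek()
                if tok == ",":
                    take()
                    node.children.append(parse_node())
                elif tok == ")":
                    take()
                    break
                else:
                    raise NewickParseError(
                        f"expected ',' or ')' at position {at}")
            tok, at = peek()
            if tok not in (None, ",", ")", ":", ";"):
                take()
                try:
                    node.support = float(tok)
                except ValueError:
                    node.name = tok
        else:
            if tok in (None, ",", ")", ";", ":"):
                raise NewickParseError(f"expected a label at position {at}")
            take()
            node.name = tok
        tok, at = peek()
        if tok == ":":
            take()
            tok, at = take()
            try:
                node.length = float(tok)
            except (TypeError, ValueError):
                raise NewickParseError(
                    f"invalid branch length at position {at}")
        return node

    root = parse_node()
    tok, at = peek()
    if tok != ";":
        raise NewickParseError(f"expected ';' at position {at}")
    return root


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text().strip())
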