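"""Unrooted binary tree topologies.

Trees are topology-only (no branch lengths): the parsimony criterion and all
annealing analyses in this package depend on topology alone.  Taxa are the
integers ``0..n-1``; internal vertices are ``n..2n-3``, so a tree over *n*
leaves always has ``2n-2`` vertices and ``2n-3`` edges.  Adjacency is held as
a ``(2n-2, 3)`` int32 array padded with -1 (leaves have one neighbour), which
keeps tree copies and full-tree rescoring cheap inside the annealing loop.
Taxon labels attach only at I/O boundaries (PHYLIP and newick).

A *split* (bipartition) is stored canonically as the side that excludes
taxon 0, as a ``frozenset`` of taxon indices.  A split is non-trivial iff
both sides contain at least two taxa; an unrooted binary tree over *n* taxa
has exactly ``n-3`` non-trivial splits, one per internal edge.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "TreeError",
    "Topology",
    "random_topology",
    "splits",
    "parse_newick",
    "write_newick",
    "robinson_foulds",
]


class TreeError(ValueError):
    """Invalid tree structure or malformed newick input."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class Topology:
    """Unrooted binary tree over taxa ``0..n_taxa-1``.

    Parameters
    ----------
    n_taxa : int
        Number of leaves.
    adj : (2*n_taxa-2, 3) int32 array
        Adjacency rows padded with -1.  Leaves (rows ``0..n_taxa-1``) have one
        neighbour; internal vertices have three.
    """

    __slots__ = ("n_taxa", "adj")

    def __init__(self, n_taxa: int, adj: np.ndarray):
        self.n_taxa = n_taxa
        self.adj = adj

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_taxa - 2

    @property
    def n_edges(self) -> int:
        return 2 * self.n_taxa - 3

    def copy(self) -> "Topology":
        return Topology(self.n_taxa, self.adj.copy())

    def neighbors(self, v: int) -> list[int]:
        return [int(u) for u in self.adj[v] if u >= 0]

    def edges(self) -> np.ndarray:
        """All edges as a (2n-3, 2) array with u < v per row."""
        m = self.adj.shape[0]
        rows = np.repeat(np.arange(m, dtype=np.int32), 3)
        flat = self.adj.ravel()
        mask = flat > rows
        return np.column_stack((rows[mask], flat[mask]))

    def internal_edges(self) -> np.ndarray:
        """Edges with both endpoints internal, as a (n-3, 2) array."""
        e = self.edges()
        return e[e[:, 0] >= self.n_taxa]

    def validate(self) -> None:
        """Raise :class:`TreeError` unless this is a valid unrooted binary tree."""
        n = self.n_taxa
        if n < 4:
            raise TreeError(f"need at least 4 taxa, got {n}")
        if self.adj.shape != (2 * n - 2, 3):
            raise TreeError("wrong adjacency shape")
        for v in range(2 * n - 2):
            nbrs = self.neighbors(v)
            want = 1 if v < n else 3
            if len(nbrs) != want:
                raise TreeError(f"vertex {v} has degree {len(nbrs)}, expected {want}")
            if len(set(nbrs)) != len(nbrs) or v in nbrs:
                raise TreeError(f"vertex {v} has repeated or self adjacency")
            for u in nbrs:
                if v not in self.neighbors(u):
                    raise TreeError(f"asymmetric adjacency {v}-{u}")
        # connectivity; with the degree sequence above this implies a tree
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for u in self.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != 2 * n - 2:
            raise TreeError("tree is not connected")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Topology(n_taxa={self.n_taxa}, {write_newick(self)})"


def _adj_from_lists(n_taxa: int, lists: Sequence[Sequence[int]]) -> np.ndarray:
    adj = np.full((2 * n_taxa - 2, 3), -1, dtype=np.int32)
    for v, nbrs in enumerate(lists):
        for k, u in enumerate(nbrs):
            adj[v, k] = u
    return adj


def random_topology(n_taxa: int, rng) -> Topology:
    """Random tree by stepwise addition.

    Starts from the three-leaf star and attaches each remaining taxon to a
    uniformly chosen existing edge.  This is the conventional "random
    topology" start for tree searches; it is uniform over topologies for
    n = 4 but not for larger n.
    """
    if n_taxa < 4:
        raise TreeError(f"random_topology requires n_taxa >= 4, got {n_taxa}")
    rng = _as_rng(rng)
    lists: list[list[int]] = [[] for _ in range(2 * n_taxa - 2)]
    c = n_taxa  # first internal vertex
    for leaf in (0, 1, 2):
        lists[leaf] = [c]
        lists[c].append(leaf)
    edges = [(0, c), (1, c), (2, c)]
    for k in range(3, n_taxa):
        i = int(rng.integers(len(edges)))
        u, v = edges[i]
        w = n_taxa + k - 2
        lists[u][lists[u].index(v)] = w
        lists[v][lists[v].index(u)] = w
        lists[w] = [u, v, k]
        lists[k] = [w]
        edges[i] = (u, w)
        edges.append((w, v))
        edges.append((k, w))
    return Topology(n_taxa, _adj_from_lists(n_taxa, lists))


def _postorder(t: Topology, root: int):
    """(order, parent) with children-before-parent when order is reversed."""
    parent = [-1] * t.n_nodes
    parent[root] = root
    order = [root]
    stack = [root]
    adj = t.adj
    n = t.n_taxa
    while stack:
        v = stack.pop()
        for u in adj[v]:
            u = int(u)
            if u >= 0 and parent[u] == -1:
                parent[u] = v
                order.append(u)
                if u >= n:
                    stack.append(u)
    return order, parent


def splits(t: Topology) -> frozenset[frozenset[int]]:
    """The ``n-3`` non-trivial splits, each as the side excluding taxon 0."""
    n = t.n_taxa
    root = int(t.adj[0, 0])
    order, parent = _postorder(t, root)
    clade: list[frozenset[int] | None] = [None] * t.n_nodes
    out = set()
    for v in reversed(order):
        if v < n:
            clade[v] = frozenset((v,))
        else:
            acc: frozenset[int] = frozenset()
            for u in t.adj[v]:
                u = int(u)
                if u >= 0 and u != parent[v]:
                    acc |= clade[u]  # type: ignore[operator]
            clade[v] = acc
        if v != root and 2 <= len(clade[v]) <= n - 2:  # type: ignore[arg-type]
            out.add(clade[v])
    return frozenset(out)


def robinson_foulds(t1: Topology, t2: Topology) -> int:
    """Symmetric-difference (Robinson–Foulds) distance between split sets."""
    if t1.n_taxa != t2.n_taxa:
        raise TreeError("leaf-set mismatch")
    return len(splits(t1) ^ splits(t2))


# ---------------------------------------------------------------------------
# newick I/O (topology-only; unrooted trees written with a basal trifurcation)
# ---------------------------------------------------------------------------

def write_newick(t: Topology, taxa: Sequence[str] | None = None) -> str:
    """Newick string with an arbitrary basal trifurcation, no branch lengths.

    Output is stable for a fixed topology and taxon order.
    """
    labels = list(taxa) if taxa is not None else [str(i) for i in range(t.n_taxa)]
    if len(labels) != t.n_taxa:
        raise TreeError("taxa label list length mismatch")
    n = t.n_taxa
    root = int(t.adj[0, 0])

    def sub(v: int, par: int) -> str:
        if v < n:
            return labels[v]
        kids = [sub(u, v) for u in t.neighbors(v) if u != par]
        return "(" + ",".join(kids) + ")"

    kids = [sub(u, root) for u in t.neighbors(root)]
    return "(" + ",".join(kids) + ");"


def _tokenize_newick(text: str):
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    special = "(),:;"

    def _skip_branch_length():
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1

    def _skip_label():
        # internal node label and/or branch length: tolerated, ignored
        nonlocal pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        _skip_branch_length()

    def parse_node():
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise TreeError("unbalanced parentheses in newick")
            pos += 1
            _skip_label()
            return tuple(children)
        start = pos
        while pos < len(s) and s[pos] not in special:
            pos += 1
        label = s[start:pos].strip()
        if not label:
            raise TreeError("empty leaf label in newick")
        _skip_branch_length()
        return label

    tree = parse_node()
    if pos != len(s):
        raise TreeError("trailing characters after newick tree")
    return tree


def parse_newick(text: str, taxa: Sequence[str]) -> Topology:
    """Parse a (possibly rooted) binary newick tree over the given taxa.

    A bifurcating root is suppressed so the result is unrooted; the top level
    may also be a trifurcation.  Branch lengths and internal labels are
    ignored.  Raises :class:`TreeError` on unbalanced parentheses, unknown or
    duplicated taxon labels, or non-binary structure.
    """
    n = len(taxa)
    idx = {lab: i for i, lab in enumerate(taxa)}
    if len(idx) != n:
        raise TreeError("duplicate labels in taxa list")
    tree = _tokenize_newick(text)
    if not isinstance(tree, tuple):
        raise TreeError("newick tree has a single leaf")
    # unroot a bifurcating root by absorbing one child's children
    if len(tree) == 2:
        a, b = tree
        if isinstance(a, tuple):
            tree = tuple(list(a) + [b])
        elif isinstance(b, tuple):
            tree = tuple(list(b) + [a])
        else:
            raise TreeError("tree has only two leaves")
    if len(tree) != 3:
        raise TreeError(f"root must be bi- or trifurcating, got {len(tree)} children")

    lists: list[list[int]] = [[] for _ in range(2 * n - 2)]
    seen_taxa: set[int] = set()
    next_internal = [n]

    def build(node, parent_id: int) -> None:
        if isinstance(node, str):
            if node not in idx:
                raise TreeError(f"unknown taxon label {node!r}")
            i = idx[node]
            if i in seen_taxa:
                raise TreeError(f"taxon {node!r} appears twice")
            seen_taxa.add(i)
            lists[i].append(parent_id)
            lists[parent_id].append(i)
            return
        if len(node) != 2:
            raise TreeError("tree is not binary")
        v = next_internal[0]
        next_internal[0] += 1
        if v >= 2 * n - 2:
            raise TreeError("too many internal vertices (tree/taxa mismatch)")
        lists[parent_id].append(v)
        lists[v].append(parent_id)
        for child in node:
            build(child, v)

    root = next_internal[0]
    next_internal[0] += 1
    for child in tree:
        build(child, root)
    if len(seen_taxa) != n:
        missing = sorted(set(range(n)) - seen_taxa)
        raise TreeError(f"taxa missing from newick: {[taxa[i] for i in missing]}")
    t = Topology(n, _adj_from_lists(n, lists))
    t.validate()
    return t


def topology_key(t: Topology) -> frozenset[frozenset[int]]:
    """Canonical hashable identity: two topologies are isomorphic iff equal keys."""
    return splits(t)
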