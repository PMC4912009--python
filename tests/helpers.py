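"""Independent oracles and shared utilities for the test suite.

Everything here is deliberately written without reference to the package's
production code paths: the minimum-mutation oracle enumerates ancestral
labelings by dynamic programming (Sankoff with unit costs), tree comparisons
go through pairwise leaf path lengths, and neighbourhoods are brute-forced.
"""

from __future__ import annotations

import numpy as np

from annealtree.alignment_io import Alignment
from annealtree.parsimony import IUPAC_MASKS
from annealtree.tree_model import Topology

INF = 10 ** 9


def sankoff_column(t: Topology, column_masks) -> int:
    """Minimum mutations for one column, by DP over all ancestral labelings."""
    n = t.n_taxa
    root = int(t.adj[0, 0])
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for u in t.neighbors(v):
            if u not in parent:
                parent[u] = v
                order.append(u)
                stack.append(u)
    cost: dict[int, list[int]] = {}
    for v in reversed(order):
        if v < n:
            mask = column_masks[v]
            cost[v] = [0 if (mask >> s) & 1 else INF for s in range(4)]
        else:
            kids = [u for u in t.neighbors(v) if u != parent[v]]
            acc = [0, 0, 0, 0]
            for u in kids:
                cu = cost[u]
                for s in range(4):
                    acc[s] += min(cu[x] + (0 if x == s else 1) for x in range(4))
            cost[v] = acc
    return min(cost[root])


def min_mutation_length(t: Topology, aln: Alignment) -> int:
    """Oracle tree length: per-column Sankoff DP, no pattern compression."""
    total = 0
    for j in range(aln.n_sites):
        col = [IUPAC_MASKS[row[j]] for row in aln.matrix]
        total += sankoff_column(t, col)
    return total


def path_length_matrix(t: Topology) -> np.ndarray:
    """Pairwise leaf-to-leaf edge counts (an isomorphism invariant)."""
    n = t.n_taxa
    out = np.zeros((n, n), dtype=int)
    for src in range(n):
        dist = {src: 0}
        stack = [src]
        while stack:
            v = stack.pop()
            for u in t.neighbors(v):
                if u not in dist:
                    dist[u] = dist[v] + 1
                    stack.append(u)
        for leaf in range(n):
            out[src, leaf] = dist[leaf]
    return out


def random_alignment(rng: np.random.Generator, n_taxa: int, n_sites: int,
                     ambig_frac: float = 0.0, name: str = "rand") -> Alignment:
    """Uniform random matrix over ACGT with optional ambiguity characters."""
    bases = np.array(list("ACGT"))
    mat = rng.choice(bases, size=(n_taxa, n_sites))
    if ambig_frac > 0:
        extra = np.array(list("RYSWKMBDHVN-?"))
        hit = rng.random((n_taxa, n_sites)) < ambig_frac
        mat[hit] = rng.choice(extra, size=int(hit.sum()))
    taxa = tuple(f"x{i}" for i in range(n_taxa))
    return Alignment(taxa, tuple("".join(row) for row in mat), name=name)
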