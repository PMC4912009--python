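"""Tree length by Fitch's algorithm and the homoplasy-index cost function.

For a column of nucleotide observations, Fitch's post-order pass computes the
minimum number of substitutions required on a given topology (intersection of
child state-sets where non-empty, otherwise union plus one change).  Summed
over columns this gives the tree length ``L``.

The data-determined lower bound ``K`` is the sum over columns of each
column's tree-independent minimum change count, so the consistency index
``CI = K / L`` lies in (0, 1] and the homoplasy index ``HI = 1 - CI`` is the
quantity the annealing search minimises.  ``K`` doubles as the Boltzmann
constant of the Metropolis rule, since

    HI_current - HI_candidate = K (1/L_candidate - 1/L_current),

and may therefore be scaled by a free multiplier ``c`` for experiments on the
acceptance rule without touching the data.

State sets are encoded as 4-bit masks (A=1, C=2, G=4, T=8); IUPAC ambiguity
codes map to their base sets and both ``-`` and ``?`` map to full ambiguity
{A,C,G,T}.  Identical site patterns are collapsed with multiplicities, which
changes no score but makes full-tree rescoring cheap enough for the
annealing inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alignment_io import Alignment
from .tree_model import Topology

__all__ = [
    "IUPAC_MASKS",
    "ScoringContext",
    "build_context",
    "min_changes_column",
    "fitch_length",
    "homoplasy_index",
    "exhaustive_search",
    "enumerate_topologies",
]

IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111, "?": 0b1111,
}

_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


@dataclass
class ScoringContext:
    """Pre-compressed alignment data for fast Fitch scoring.

    Attributes
    ----------
    leaf_masks : (n_taxa, n_patterns) uint8 array of state-set bitmasks.
    mult : (n_patterns,) int64 multiplicities; sums to ``n_sites``.
    K : int, tree-independent minimum total change count.
    c : float, Boltzmann multiplier applied to K in the cost function.
    """

    leaf_masks: np.ndarray
    mult: np.ndarray
    K: int
    c: float
    n_taxa: int
    n_sites: int
    taxa: tuple[str, ...]
    name: str = "alignment"
    _buf: np.ndarray = field(init=False, repr=False)
    _score_mult: np.ndarray = field(init=False, repr=False)
    _const_length: int = field(init=False, repr=False)

    def __post_init__(self):
        if int(self.mult.sum()) != self.n_sites:
            raise ValueError("pattern multiplicities must sum to n_sites")
        if (self.leaf_masks == 0).any():
            raise ValueError("empty leaf state-set")
        # Parsimony-uninformative patterns (every taxon a single base, at most
        # one base occurring more than once) score (distinct bases - 1) on
        # every topology; pull their contribution out as a constant so the
        # Fitch kernel only visits patterns whose length depends on the tree.
        const_len = 0
        informative = np.ones(self.leaf_masks.shape[1], dtype=bool)
        for j in range(self.leaf_masks.shape[1]):
            col = self.leaf_masks[:, j]
            if (_POPCOUNT[col] != 1).any():
                continue
            vals, cnt = np.unique(col, return_counts=True)
            if (cnt >= 2).sum() <= 1:
                informative[j] = False
                const_len += (len(vals) - 1) * int(self.mult[j])
        object.__setattr__(self, "_const_length", const_len)
        score_mult = np.where(informative, self.mult, 0).astype(np.int64)
        keep = score_mult > 0
        object.__setattr__(self, "_score_mult", score_mult[keep])
        # scratch buffer for Fitch passes: leaves fixed, internals overwritten
        buf = np.empty((2 * self.n_taxa - 2, int(keep.sum())), dtype=np.uint8)
        buf[: self.n_taxa] = self.leaf_masks[:, keep]
        object.__setattr__(self, "_buf", buf)

    @property
    def effective_k(self) -> float:
        return self.c * self.K

    @property
    def n_patterns(self) -> int:
        return self.leaf_masks.shape[1]


def min_changes_column(column) -> int:
    """Tree-independent minimum changes for one column of state-sets.

    Counts the bases that are unavoidably present — those for which some
    taxon's state-set is exactly that single base — and returns
    ``max(count, 1) - 1``.  Fully or partially ambiguous taxa contribute
    nothing, so the result never exceeds the length of any tree.
    """
    masks = [_to_mask(x) for x in column]
    if not masks:
        raise ValueError("empty column")
    fixed = {m for m in masks if int(_POPCOUNT[m]) == 1}
    return max(len(fixed), 1) - 1


def _to_mask(x) -> int:
    if isinstance(x, str):
        return IUPAC_MASKS[x.upper()]
    return int(x)


def build_context(a: Alignment, c: float = 1.0) -> ScoringContext:
    """Encode, pattern-compress and bound an alignment for scoring."""
    if c <= 0:
        raise ValueError("Boltzmann multiplier c must be positive")
    if a.n_sites < 1:
        raise ValueError("alignment with zero sites")
    codes = np.empty((a.n_taxa, a.n_sites), dtype=np.uint8)
    for i, row in enumerate(a.matrix):
        codes[i] = [IUPAC_MASKS[ch] for ch in row]
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    # K per unique pattern, weighted by multiplicity
    k_total = 0
    for j in range(patterns.shape[1]):
        col = patterns[:, j]
        fixed = np.unique(col[_POPCOUNT[col] == 1])
        k_total += (max(len(fixed), 1) - 1) * int(counts[j])
    return ScoringContext(
        leaf_masks=patterns,
        mult=counts.astype(np.int64),
        K=int(k_total),
        c=float(c),
        n_taxa=a.n_taxa,
        n_sites=a.n_sites,
        taxa=a.taxa,
        name=a.name,
    )


@njit(cache=False)
def _fitch_kernel(adj, n_taxa, buf, mult):  # pragma: no cover - jitted
    n_nodes = adj.shape[0]
    n_pat = buf.shape[1]
    root = adj[0, 0]
    parent = np.full(n_nodes, -2, np.int32)
    parent[root] = 0  # leaf 0 is root's "parent": roots the tree on that edge
    order = np.empty(n_nodes, np.int32)
    order[0] = root
    stack = np.empty(n_nodes, np.int32)
    stack[0] = root
    sp = 1
    cnt = 1
    while sp > 0:
        sp -= 1
        v = stack[sp]
        for k in range(3):
            u = adj[v, k]
            if u < 0:
                continue
            if parent[u] == -2:
                parent[u] = v
                order[cnt] = u
                cnt += 1
                if u >= n_taxa:
                    stack[sp] = u
                    sp += 1
    total = 0
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if v < n_taxa:
            continue
        c0 = -1
        c1 = -1
        for k in range(3):
            u = adj[v, k]
            if u >= 0 and u != parent[v]:
                if c0 < 0:
                    c0 = u
                else:
                    c1 = u
        for j in range(n_pat):
            m = buf[c0, j] & buf[c1, j]
            if m == 0:
                total += mult[j]
                buf[v, j] = buf[c0, j] | buf[c1, j]
            else:
                buf[v, j] = m
    for j in range(n_pat):
        if buf[0, j] & buf[root, j] == 0:
            total += mult[j]
    return total


def fitch_length(t: Topology, ctx: ScoringContext) -> int:
    """Tree length: minimum substitutions for the alignment on topology ``t``.

    Standard Fitch post-order pass, rooted on the edge adjacent to taxon 0;
    the result is independent of the rooting choice.  Parsimony-uninformative
    patterns contribute a precomputed tree-independent constant.
    """
    if t.n_taxa != ctx.n_taxa:
        raise ValueError("topology leaf set does not match scoring context")
    variable = int(_fitch_kernel(t.adj, ctx.n_taxa, ctx._buf, ctx._score_mult))
    return ctx._const_length + variable


def homoplasy_index(L: int, ctx: ScoringContext) -> float:
    """HI = 1 - CI with CI = cK / L; the annealing cost.

    The degenerate case ``L = 0`` (constant data, forcing ``K = 0``) is
    defined as CI = 1, HI = 0.  ``L < K`` is impossible by theory and raises.
    """
    if L < 0:
        raise ValueError("negative tree length")
    if L == 0:
        return 0.0
    if L < ctx.K:
        raise ValueError(f"tree length {L} below theoretical minimum K={ctx.K}")
    return 1.0 - ctx.effective_k / L


# ---------------------------------------------------------------------------
# exhaustive enumeration (test/benchmark oracle; (2n-5)!! topologies)
# ---------------------------------------------------------------------------

def enumerate_topologies(n_taxa: int):
    """Yield every unrooted binary topology over ``n_taxa`` leaves.

    Recursive edge-addition; (2n-5)!! trees, so callers should keep n small.
    """
    if n_taxa < 4:
        raise ValueError("enumeration requires n_taxa >= 4")

    def rec(edges: list[tuple[int, int]], next_internal: int, k: int):
        if k == n_taxa:
            yield _from_edges(n_taxa, edges)
            return
        w = next_internal
        for i in range(len(edges)):
            u, v = edges[i]
            new_edges = edges[:i] + [(u, w), (w, v), (k, w)] + edges[i + 1:]
            yield from rec(new_edges, w + 1, k + 1)

    c = n_taxa
    yield from rec([(0, c), (1, c), (2, c)], c + 1, 3)


def _from_edges(n_taxa: int, edges) -> Topology:
    adj = np.full((2 * n_taxa - 2, 3), -1, dtype=np.int32)
    fill = np.zeros(2 * n_taxa - 2, dtype=np.int8)
    for u, v in edges:
        adj[u, fill[u]] = v
        fill[u] += 1
        adj[v, fill[v]] = u
        fill[v] += 1
    return Topology(n_taxa, adj)


def exhaustive_search(a: Alignment, c: float = 1.0):
    """Optimal tree length and all optimal topologies by full enumeration.

    Refuses ``n_taxa > 9`` (135,135 topologies at n = 9 is the practical
    ceiling for an exact search on one core).
    """
    if a.n_taxa > 9:
        raise ValueError(f"exhaustive search limited to 9 taxa, got {a.n_taxa}")
    if a.n_taxa < 4:
        raise ValueError("exhaustive search requires at least 4 taxa")
    ctx = build_context(a, c=c)
    best = None
    winners: list[Topology] = []
    for t in enumerate_topologies(a.n_taxa):
        L = fitch_length(t, ctx)
        if best is None or L < best:
            best = L
            winners = [t]
        elif L == best:
            winners.append(t)
    return best, winners
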