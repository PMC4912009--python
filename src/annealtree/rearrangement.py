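"""Candidate proposal by NNI and SPR, offered in strict alternation.

NNI picks a uniform random internal edge and one of its two alternative
subtree arrangements.  SPR picks a uniform random edge, prunes the subtree on
one side, and regrafts it onto a uniformly chosen eligible edge of the
remaining tree; regrafts that would re-create the source topology are
excluded, so every proposal is a genuine perturbation.  Alternation starts
with NNI (even move index -> NNI, odd -> SPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree_model import Topology, _as_rng

__all__ = [
    "MoveProposal",
    "nni_neighbor",
    "spr_neighbor",
    "alternating_proposer",
    "all_nni_neighbors",
    "all_spr_neighbors",
]


@dataclass
class MoveProposal:
    kind: str  # "NNI" or "SPR"
    topology: Topology
    detail: tuple  # edited edges, for logging


def _replace(adj: np.ndarray, u: int, old: int, new: int) -> None:
    row = adj[u]
    for k in range(3):
        if row[k] == old:
            row[k] = new
            return
    raise RuntimeError(f"vertex {u} not adjacent to {old}")


def _others(adj: np.ndarray, u: int, excl: int) -> list[int]:
    return [int(x) for x in adj[u] if x >= 0 and x != excl]


def _apply_nni(t: Topology, u: int, v: int, arrangement: int) -> Topology:
    """Swap one subtree across internal edge (u, v); arrangement in {0, 1}."""
    new = t.copy()
    adj = new.adj
    b = _others(adj, u, v)[1]
    c = _others(adj, v, u)[arrangement]
    _replace(adj, u, b, c)
    _replace(adj, v, c, b)
    _replace(adj, b, u, v)
    _replace(adj, c, v, u)
    return new


def nni_neighbor(t: Topology, rng) -> MoveProposal:
    rng = _as_rng(rng)
    internal = t.internal_edges()
    u, v = (int(x) for x in internal[int(rng.integers(len(internal)))])
    arrangement = int(rng.integers(2))
    return MoveProposal("NNI", _apply_nni(t, u, v, arrangement), ((u, v), arrangement))


def all_nni_neighbors(t: Topology) -> list[Topology]:
    """Deterministic enumeration of the full NNI neighbourhood, size 2(n-3)."""
    out = []
    for u, v in t.internal_edges():
        for arrangement in (0, 1):
            out.append(_apply_nni(t, int(u), int(v), arrangement))
    return out


def _component_edges(adj: np.ndarray, starts, banned: int) -> list[tuple[int, int]]:
    """Edges reachable from ``starts`` without crossing vertex ``banned``."""
    seen = set(starts)
    stack = list(starts)
    edges = []
    while stack:
        x = stack.pop()
        for y in adj[x]:
            y = int(y)
            if y < 0 or y == banned:
                continue
            if x < y:
                edges.append((x, y))
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return edges


def _spr_prune_regraft(t: Topology, s: int, a: int, c: int, d: int) -> Topology:
    """Prune the subtree rooted at ``s`` across edge (s, a); regraft onto (c, d).

    The degree-2 vertex ``a`` left by pruning is suppressed and reused as the
    new attachment vertex.
    """
    new = t.copy()
    adj = new.adj
    x, y = _others(adj, a, s)
    _replace(adj, x, a, y)
    _replace(adj, y, a, x)
    _replace(adj, c, d, a)
    _replace(adj, d, c, a)
    adj[a, 0] = c
    adj[a, 1] = d
    adj[a, 2] = s
    # s keeps its pointer to a
    return new


def _spr_options(t: Topology, s: int, a: int):
    """Eligible regraft edges after pruning side ``s`` of edge (s, a)."""
    if a < t.n_taxa:
        return None  # cannot suppress a leaf attachment point
    x, y = _others(t.adj, a, s)
    # after suppressing a, the remaining tree is the two components either
    # side of a joined by the merged edge (x, y); regrafting onto that merged
    # edge would re-create the source topology, and it is never a real edge
    # of t, so the eligible set is exactly the surviving original edges
    eligible = _component_edges(t.adj, (x, y), banned=a)
    return eligible or None


def spr_neighbor(t: Topology, rng) -> MoveProposal:
    rng = _as_rng(rng)
    edges = t.edges()
    while True:
        u, v = (int(x) for x in edges[int(rng.integers(len(edges)))])
        s, a = (u, v) if rng.integers(2) == 0 else (v, u)
        eligible = _spr_options(t, s, a)
        if eligible is None:
            continue  # no eligible regraft edge: re-draw the pruned edge
        c, d = eligible[int(rng.integers(len(eligible)))]
        return MoveProposal(
            "SPR", _spr_prune_regraft(t, s, a, c, d), ((s, a), (c, d))
        )


def all_spr_neighbors(t: Topology) -> list[Topology]:
    """Every topology reachable by one eligible prune-and-regraft."""
    out = []
    for u, v in t.edges():
        for s, a in ((int(u), int(v)), (int(v), int(u))):
            eligible = _spr_options(t, s, a)
            if eligible is None:
                continue
            for c, d in eligible:
                out.append(_spr_prune_regraft(t, s, a, c, d))
    return out


def alternating_proposer(t: Topology, move_index: int, rng) -> MoveProposal:
    """Even move index -> NNI, odd -> SPR (strict alternation, NNI first)."""
    if move_index % 2 == 0:
        return nni_neighbor(t, rng)
    return spr_neighbor(t, rng)
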