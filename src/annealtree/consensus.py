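"""Strict consensus trees and temperature-stratified convergence analysis.

The strict consensus of a set of trees contains exactly the splits present in
every input tree; its *resolution* is the fraction of the ``n - 3`` possible
internal splits it retains (1 for a fully binary tree, 0 for a star).
Computed per sampled temperature of an annealing run, the resolution series
exposes the trapping behaviour around the critical temperature: above it the
sampled trees share little structure, below it they converge to one family
of similar topologies.

Consensus is computed on unrooted splits; rooting (on an outgroup) is for
display only and never feeds back into scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .annealing import RunTrace
from .tree_model import Topology, TreeError, splits

__all__ = [
    "ConsensusTree",
    "ConsensusSeries",
    "strict_consensus",
    "resolution",
    "consensus_series",
    "consensus_series_from_samples",
    "consensus_newick",
    "root_for_display",
]


@dataclass(frozen=True)
class ConsensusTree:
    """Possibly multifurcating unrooted tree, held as its compatible split set."""

    n_taxa: int
    splits: frozenset[frozenset[int]]

    def __post_init__(self):
        for s in self.splits:
            if not (2 <= len(s) <= self.n_taxa - 2):
                raise TreeError("trivial or empty split in consensus")


def strict_consensus(trees: Sequence[Topology]) -> ConsensusTree:
    """Consensus containing exactly the splits shared by every input tree."""
    if not trees:
        raise TreeError("strict consensus of an empty tree list")
    n = trees[0].n_taxa
    if any(t.n_taxa != n for t in trees):
        raise TreeError("leaf-set mismatch among input trees")
    common = splits(trees[0])
    for t in trees[1:]:
        common = common & splits(t)
        if not common:
            break
    return ConsensusTree(n_taxa=n, splits=frozenset(common))


def resolution(ct: ConsensusTree) -> float:
    """|splits| / (n - 3): 1 for fully binary, 0 for a star."""
    if ct.n_taxa < 4:
        raise TreeError("resolution undefined below 4 taxa")
    return len(ct.splits) / (ct.n_taxa - 3)


def _mean_pairwise_rf(trees: Sequence[Topology]) -> float:
    if len(trees) < 2:
        return 0.0
    ss = [splits(t) for t in trees]
    dists = [len(a ^ b) for a, b in combinations(ss, 2)]
    return float(np.mean(dists))


@dataclass
class ConsensusSeries:
    """Per sampled temperature: consensus tree, resolution, mean pairwise RF."""

    temperatures: list[float]
    trees: list[ConsensusTree]
    resolutions: list[float]
    mean_rf: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.temperatures,
            "resolution": self.resolutions,
            "mean_rf": self.mean_rf,
        })


def consensus_series(trace: RunTrace) -> ConsensusSeries:
    """Consensus/resolution/RF at every temperature where trees were sampled."""
    samples = [(blk.T, blk.topologies) for blk in trace.blocks if blk.topologies]
    if not samples:
        raise ValueError("trace holds no sampled topologies")
    return consensus_series_from_samples(samples)


def consensus_series_from_samples(samples: Sequence[tuple[float, Sequence[Topology]]]) -> ConsensusSeries:
    series = ConsensusSeries([], [], [], [])
    for T, trees in samples:
        ct = strict_consensus(list(trees))
        series.temperatures.append(float(T))
        series.trees.append(ct)
        series.resolutions.append(resolution(ct))
        series.mean_rf.append(_mean_pairwise_rf(list(trees)))
    return series


# ---------------------------------------------------------------------------
# newick rendering of (possibly multifurcating) split sets, and display rooting
# ---------------------------------------------------------------------------

def _cluster_newick(members: frozenset[int], clades: list[frozenset[int]],
                    labels: Sequence[str]) -> str:
    """Render a clade by nesting the maximal sub-clades inside it."""
    inner = [c for c in clades if c < members]
    maximal = [c for c in inner if not any(c < d for d in inner)]
    covered: set[int] = set()
    parts: list[tuple[int, str]] = []
    for c in maximal:
        parts.append((min(c), _cluster_newick(c, inner, labels)))
        covered |= set(c)
    for leaf in members - covered:
        parts.append((leaf, labels[leaf]))
    parts.sort()
    rendered = [s for _, s in parts]
    if len(rendered) == 1:
        return rendered[0]
    return "(" + ",".join(rendered) + ")"


def consensus_newick(ct: ConsensusTree, taxa: Sequence[str] | None = None) -> str:
    """Unrooted newick: taxon 0 and its sister structure at the base."""
    labels = list(taxa) if taxa is not None else [str(i) for i in range(ct.n_taxa)]
    everyone = frozenset(range(ct.n_taxa))
    clades = list(ct.splits)  # all exclude taxon 0 by canonical form
    body = _cluster_newick(everyone - {0}, clades, labels)
    return f"({labels[0]},{body});"


def _all_sides(n_taxa: int, split_set) -> list[frozenset[int]]:
    """Both orientations of every edge-defining bipartition, plus trivial sides."""
    everyone = frozenset(range(n_taxa))
    sides = set()
    for s in split_set:
        sides.add(s)
        sides.add(everyone - s)
    for i in range(n_taxa):
        sides.add(frozenset((i,)))
        sides.add(everyone - {i})
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


def root_for_display(t, outgroup: Sequence[int],
                     taxa: Sequence[str] | None = None) -> str:
    """Rooted newick for figures: root on the edge separating the outgroup.

    If the outgroup is monophyletic (it equals one side of an edge) the tree
    is rooted on that edge.  Otherwise the root edge is the side containing
    the most outgroup taxa, smallest first, ties broken by the lowest
    canonical split — a deterministic fallback.  Display only.
    """
    og = frozenset(outgroup)
    if isinstance(t, ConsensusTree):
        n, split_set = t.n_taxa, t.splits
    else:
        n, split_set = t.n_taxa, splits(t)
    everyone = frozenset(range(n))
    if not og or not (og < everyone):
        raise TreeError("outgroup must be a non-empty proper subset of the taxa")
    sides = _all_sides(n, split_set)
    exact = [s for s in sides if s == og]
    if exact:
        side = exact[0]
    else:
        best_overlap = max(len(s & og) for s in sides)
        candidates = [s for s in sides if len(s & og) == best_overlap]
        side = min(candidates, key=lambda s: (len(s), sorted(s)))
    labels = list(taxa) if taxa is not None else [str(i) for i in range(n)]
    clades = [s for s in _all_sides(n, split_set) if 1 < len(s) < n]
    left = _cluster_newick(side, [c for c in clades if c < side], labels) \
        if len(side) > 1 else labels[next(iter(side))]
    comp = everyone - side
    right = _cluster_newick(comp, [c for c in clades if c < comp], labels) \
        if len(comp) > 1 else labels[next(iter(comp))]
    return f"({left},{right});"
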