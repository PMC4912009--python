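"""Synthetic alignments with controlled tree signal and homoplasy.

Sequences evolve on a known (given or random) unrooted binary topology under
the simplest useful substitution process: along each branch, independently
per site, a substitution occurs with probability ``p`` and replaces the base
with one of the three other bases uniformly (an equal-rates, Jukes–Cantor-
like process applied as a per-branch probability).  ``p`` tunes homoplasy:
near 0 the data are nearly clean (CI of the optimal tree approaches 1), and
as ``p`` grows toward the 0.75 saturation point the optimal tree accumulates
homoplasy and CI drops well below 1.

The module also builds a catalogue of tiny hand-checkable alignments whose
optimal lengths and topologies are certified by exhaustive enumeration at
call time — the ground truth for search and scoring tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment
from .parsimony import build_context, exhaustive_search
from .tree_model import Topology, random_topology, _postorder

__all__ = ["SimulationParams", "evolve_alignment", "toy_fixtures", "ToyFixture"]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    p is the per-branch, per-site substitution probability; it must stay
    below 0.75, the fixed point of the equal-rates model beyond which more
    "substitution" no longer adds divergence.
    """

    n_taxa: int
    n_sites: int
    topology: Topology | None = None
    p: float = 0.05
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        if not (0.0 <= self.p < 0.75):
            raise ValueError("substitution probability p must lie in [0, 0.75)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


def evolve_alignment(params: SimulationParams) -> tuple[Alignment, Topology]:
    """Evolve sequences on a tree; returns the alignment and generating topology."""
    rng = np.random.default_rng(params.seed)
    t = params.topology if params.topology is not None else random_topology(params.n_taxa, rng)
    if t.n_taxa != params.n_taxa:
        raise ValueError("topology size does not match n_taxa")
    n, m = params.n_taxa, params.n_sites
    root = t.adj[0][0]  # arbitrary internal vertex
    order, parent = _postorder(t, root)
    seqs = np.empty((t.n_nodes, m), dtype=np.int8)
    seqs[root] = rng.choice(4, size=m, p=params.base_freqs)
    for v in order[1:]:  # preorder: parents before children
        parent_seq = seqs[parent[v]]
        hit = rng.random(m) < params.p
        shift = rng.integers(1, 4, size=m, dtype=np.int8)
        child = parent_seq.copy()
        child[hit] = (parent_seq[hit] + shift[hit]) % 4
        seqs[v] = child
    taxa = tuple(f"t{i:03d}" for i in range(n))
    matrix = tuple("".join(_BASES[b] for b in seqs[i]) for i in range(n))
    return Alignment(taxa, matrix, name=params.name), t


@dataclass
class ToyFixture:
    """A tiny alignment with an exhaustively certified optimum."""

    alignment: Alignment
    K: int
    optimal_length: int
    optimal_topologies: list[Topology]
    generating_topology: Topology | None = None


def _fixture(alignment: Alignment, generating: Topology | None = None) -> ToyFixture:
    ctx = build_context(alignment)
    best, winners = exhaustive_search(alignment)
    return ToyFixture(alignment, ctx.K, best, winners, generating)


def toy_fixtures() -> dict[str, ToyFixture]:
    """Catalogue of named small alignments, certified at call time.

    ``quartet_clean``
        4 taxa, 3 columns all compatible with one split; K = 3 = optimal L,
        unique optimal quartet.
    ``six_clean``
        6 taxa, homoplasy-free caterpillar data; optimal L = K, unique
        optimal topology (the generating tree).
    ``six_conflict``
        6 taxa with equally weighted support for the incompatible splits
        {0,1} and {0,2}; at least two equally parsimonious topologies.
    """
    out = {}
    out["quartet_clean"] = _fixture(Alignment(
        ("a", "b", "c", "d"),
        ("AGA", "AGA", "CTG", "CTG"),
        name="quartet_clean",
    ))
    # caterpillar splits {0,1}, {0,1,2}, {4,5}; two clean columns per split
    # plus two constant columns
    out["six_clean"] = _fixture(Alignment(
        ("s0", "s1", "s2", "s3", "s4", "s5"),
        (
            "CC GG AA AA".replace(" ", ""),
            "CC GG AA AA".replace(" ", ""),
            "AA GG AA AA".replace(" ", ""),
            "AA TT AA AA".replace(" ", ""),
            "AA TT CC AA".replace(" ", ""),
            "AA TT CC AA".replace(" ", ""),
        ),
        name="six_clean",
    ))
    # equal support for {0,1} vs {0,2}, plus agreed support for {4,5}
    out["six_conflict"] = _fixture(Alignment(
        ("s0", "s1", "s2", "s3", "s4", "s5"),
        (
            "CC CC AA".replace(" ", ""),
            "CC AA AA".replace(" ", ""),
            "AA CC AA".replace(" ", ""),
            "AA AA AA".replace(" ", ""),
            "AA AA CC".replace(" ", ""),
            "AA AA CC".replace(" ", ""),
        ),
        name="six_conflict",
    ))
    return out
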