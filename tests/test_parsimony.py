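import numpy as np
import pytest

from annealtree.alignment_io import Alignment
from annealtree.parsimony import (build_context, enumerate_topologies,
                                  exhaustive_search, fitch_length,
                                  homoplasy_index, min_changes_column)
from annealtree.tree_model import parse_newick, random_topology, topology_key
from helpers import min_mutation_length, random_alignment

TAXA4 = ["A", "B", "C", "D"]


def quartet(text):
    return parse_newick(text, TAXA4)


@pytest.mark.parametrize("column, expected", [
    ("AACC", 1),
    ("ACGT", 3),
    ("AAN-", 0),
    ("AAAA", 0),
    ("A?N-", 0),
    ("ACNN", 1),
])
def test_min_changes_column(column, expected):
    assert min_changes_column(list(column)) == expected


def test_context_compression_counts():
    a = Alignment(tuple("abcd"), ("AAACCGAA", "AAACCGAA", "CCCAAGCC", "CCCAAGCC"))
    ctx = build_context(a)
    assert ctx.n_patterns == 3
    assert sorted(ctx.mult.tolist()) == [1, 2, 5]
    assert ctx.mult.sum() == 8


def test_constant_alignment_k_zero_and_hi_zero():
    a = Alignment(tuple("abcd"), ("AAAA",) * 4)
    ctx = build_context(a)
    assert ctx.K == 0
    t = quartet("((A,B),(C,D));")
    assert fitch_length(t, ctx) == 0
    assert homoplasy_index(0, ctx) == 0.0


def test_boltzmann_multiplier_scales_effective_k_only():
    a = Alignment(tuple("abcd"), ("AACC", "AACC", "CCAA", "CCAA"))
    c1 = build_context(a)
    c2 = build_context(a, c=2.0)
    assert c2.K == c1.K
    assert c2.effective_k == 2 * c1.effective_k


def test_fitch_quartet_hand_cases():
    a = Alignment(tuple("abcd"), ("A", "A", "C", "C"))
    ctx = build_context(a)
    assert fitch_length(quartet("((A,B),(C,D));"), ctx) == 1
    assert fitch_length(quartet("((A,C),(B,D));"), ctx) == 2
    b = Alignment(tuple("abcd"), ("A", "C", "G", "T"))
    ctxb = build_context(b)
    for text in ("((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"):
        assert fitch_length(quartet(text), ctxb) == 3


def test_fitch_matches_labeling_oracle_small_random(rng):
    for _ in range(40):
        n = int(rng.integers(4, 8))
        a = random_alignment(rng, n, int(rng.integers(1, 21)), ambig_frac=0.1)
        ctx = build_context(a)
        t = random_topology(n, rng)
        L = fitch_length(t, ctx)
        assert L == min_mutation_length(t, a)
        assert L >= ctx.K


def test_root_independence_via_oracle(rng):
    """The oracle DP roots at every internal vertex; all agree with Fitch."""
    from annealtree.parsimony import IUPAC_MASKS
    from helpers import sankoff_column

    a = random_alignment(rng, 6, 10, ambig_frac=0.15)
    ctx = build_context(a)
    t = random_topology(6, rng)
    L = fitch_length(t, ctx)
    for root_shift in range(6, 10):  # every internal vertex as DP root
        total = 0
        for j in range(a.n_sites):
            col = [IUPAC_MASKS[row[j]] for row in a.matrix]
            total += _rooted_sankoff(t, root_shift, col)
        assert total == L


def _rooted_sankoff(t, root, column_masks):
    INF = 10 ** 9
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
    cost = {}
    for v in reversed(order):
        if v < t.n_taxa:
            cost[v] = [0 if (column_masks[v] >> s) & 1 else INF for s in range(4)]
        else:
            acc = [0, 0, 0, 0]
            for u in (x for x in t.neighbors(v) if x != parent[v]):
                cu = cost[u]
                for s in range(4):
                    acc[s] += min(cu[x] + (x != s) for x in range(4))
            cost[v] = acc
    return min(cost[root])


def test_pattern_compression_changes_no_score(rng):
    """Scores match a per-column oracle that never compresses patterns."""
    for _ in range(10):
        a = random_alignment(rng, 6, 30)
        dup = Alignment(a.taxa, tuple(row + row for row in a.matrix))
        ctx, ctx2 = build_context(a), build_context(dup)
        t = random_topology(6, rng)
        assert fitch_length(t, ctx2) == 2 * fitch_length(t, ctx)
        assert fitch_length(t, ctx) == min_mutation_length(t, a)


def test_homoplasy_index_arithmetic():
    a = Alignment(tuple("abcd"), ("AACCG", "AACCG", "CCAAG", "CCGGG"))
    ctx = build_context(a)
    assert homoplasy_index(ctx.K, ctx) == 0.0
    assert homoplasy_index(2 * ctx.K, ctx) == 0.5
    with pytest.raises(ValueError):
        homoplasy_index(ctx.K - 1, ctx)


def test_enumeration_counts():
    assert len(list(enumerate_topologies(4))) == 3
    trees6 = list(enumerate_topologies(6))
    assert len(trees6) == 105
    assert len({topology_key(t) for t in trees6}) == 105


def test_exhaustive_search_size_limit(rng):
    a = random_alignment(rng, 10, 5)
    with pytest.raises(ValueError):
        exhaustive_search(a)


def test_homoplasy_free_data_recovers_generating_tree():
    from annealtree.synthetic_data import SimulationParams, evolve_alignment

    # low-p evolution on 7 taxa: optimum should be close to clean
    aln, truth = evolve_alignment(SimulationParams(7, 300, p=0.01, seed=5))
    ctx = build_context(aln)
    best, winners = exhaustive_search(aln)
    assert best >= ctx.K
    keys = {topology_key(w) for w in winners}
    assert topology_key(truth) in keys
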