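import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from annealtree.annealing import (AnnealConfig, Schedule,
                                  acceptance_probability,
                                  acceptance_rate_curve, anneal, save_trace)
from annealtree.parsimony import (build_context, enumerate_topologies,
                                  fitch_length, homoplasy_index)
from annealtree.synthetic_data import SimulationParams, evolve_alignment
from annealtree.tree_model import random_topology, topology_key


@pytest.mark.parametrize("delta, T, expected", [
    (0.0, 0.01, 1.0),
    (-0.05, 0.01, 1.0),
    (-0.05, 1e3, 1.0),
    (0.02, 0.02, math.exp(-1)),
    (0.5, 0.0, 0.0),
    (-0.5, 0.0, 1.0),
])
def test_acceptance_probability_closed_forms(delta, T, expected):
    assert acceptance_probability(delta, T) == pytest.approx(expected)


def test_schedule_validation():
    with pytest.raises(ValueError):
        Schedule(kind="linear", t0=-1.0)
    with pytest.raises(ValueError):
        Schedule(kind="geometric", alpha=1.2)
    with pytest.raises(ValueError):
        AnnealConfig(n=2000, l=7)  # l must divide n


@pytest.fixture(scope="module")
def small_ctx():
    aln, _ = evolve_alignment(SimulationParams(8, 200, p=0.08, seed=21, name="syn8a"))
    return build_context(aln)


@pytest.fixture(scope="module")
def default_trace(small_ctx):
    """One run under default n=2000, l=10 with a short linear schedule."""
    cfg = AnnealConfig(schedule=Schedule(kind="linear", t0=5e-4, m=1e-5),
                       seed=11, record_decisions=True)
    return anneal(small_ctx, cfg)


def test_block_structure_and_accounting(default_trace, small_ctx):
    trace = default_trace
    assert 1 <= len(trace.blocks) <= 50
    temps = [b.T for b in trace.blocks]
    assert all(a > b for a, b in zip(temps, temps[1:]))
    for blk in trace.blocks:
        assert blk.proposed_count == 2000
        assert len(blk.hi_samples) == 200
        assert blk.nni_count == blk.spr_count == 1000
        assert 0 <= blk.accepted_count <= 2000
    assert trace.termination in ("frozen", "floor", "budget")
    final_hi = homoplasy_index(fitch_length(trace.final_topology, small_ctx),
                               small_ctx)
    assert trace.best_hi <= final_hi + 1e-12


def test_trace_determinism(small_ctx):
    cfg = AnnealConfig(schedule=Schedule(kind="linear", t0=5e-4, m=2e-5),
                       n=500, l=10, seed=3, record_decisions=True)
    t1 = anneal(small_ctx, cfg)
    t2 = anneal(small_ctx, cfg)
    assert t1.hi_frame().to_csv(index=False) == t2.hi_frame().to_csv(index=False)
    assert np.array_equal(t1.decisions, t2.decisions)
    assert topology_key(t1.final_topology) == topology_key(t2.final_topology)


def test_near_zero_temperature_is_pure_descent(small_ctx):
    cfg = AnnealConfig(schedule=Schedule(kind="constant", t0=1e-9),
                       n=2000, l=10, total_move_budget=2000, seed=5)
    trace = anneal(small_ctx, cfg)
    hi = trace.blocks[0].hi_samples
    # HI of the working state never rises at (effectively) zero temperature,
    # except for cost-neutral plateau moves which leave it unchanged
    assert all(b <= a + 1e-12 for a, b in zip(hi, hi[1:]))


def test_budget_termination_counts_exactly(small_ctx):
    cfg = AnnealConfig(schedule=Schedule(kind="geometric", t0=1e-3, alpha=0.95),
                       n=500, l=10, freeze_window=None, total_move_budget=1750,
                       seed=2)
    trace = anneal(small_ctx, cfg)
    assert trace.termination == "budget"
    assert sum(b.proposed_count for b in trace.blocks) == 1750


def test_tree_sampling_only_at_designated_temperatures(small_ctx):
    temps = (5e-4, 3e-4, 1e-4)
    cfg = AnnealConfig(schedule=Schedule(kind="linear", t0=5e-4, m=2e-5),
                       n=500, l=10, l_tree=100, freeze_window=None,
                       sample_tree_temperatures=temps, seed=8)
    trace = anneal(small_ctx, cfg)
    sampled = [b for b in trace.blocks if b.topologies]
    assert len(sampled) == 3
    for blk in sampled:
        assert len(blk.topologies) == 5  # n / l_tree


def test_metropolis_stationary_distribution_matches_boltzmann():
    """Long NNI-only run at constant T visits topologies ~ exp(-HI/T).

    The NNI kernel is symmetric, so Metropolis acceptance makes the Boltzmann
    distribution over the 15 five-taxon topologies stationary; a seeded run
    should rank-correlate strongly with it.
    """
    aln, _ = evolve_alignment(SimulationParams(5, 60, p=0.3, seed=13, name="syn5"))
    ctx = build_context(aln)
    all_trees = list(enumerate_topologies(5))
    his = {topology_key(t): homoplasy_index(fitch_length(t, ctx), ctx)
           for t in all_trees}
    spread = max(his.values()) - min(his.values())
    T = spread / 3
    cfg = AnnealConfig(schedule=Schedule(kind="constant", t0=T),
                       n=60_000, l=10, l_tree=10, proposer="nni",
                       total_move_budget=60_000, freeze_window=None,
                       sample_tree_temperatures=(T,), seed=17)
    trace = anneal(ctx, cfg)
    counts = {k: 0 for k in his}
    for top in trace.blocks[0].topologies:
        counts[topology_key(top)] += 1
    keys = list(his)
    weights = [math.exp(-his[k] / T) for k in keys]
    visits = [counts[k] for k in keys]
    rho, _ = spearmanr(weights, visits)
    assert rho > 0.8


def test_acceptance_rate_curve_monotone(small_ctx, rng):
    states = [random_topology(8, rng) for _ in range(3)]
    temps = [1e-5, 1e-4, 1e-3, 1e-2, 1e3]
    rates = acceptance_rate_curve(small_ctx, states, temps, n_proposals=60, seed=4)
    assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.999  # T -> infinity limit


def test_save_trace_roundtrip(tmp_path, small_ctx):
    temps = (5e-4, 2e-4)
    cfg = AnnealConfig(schedule=Schedule(kind="linear", t0=5e-4, m=2e-5),
                       n=200, l=10, l_tree=100, freeze_window=None,
                       sample_tree_temperatures=temps, seed=1)
    trace = anneal(small_ctx, cfg)
    taxa = small_ctx.taxa
    paths = save_trace(trace, tmp_path, taxa=taxa)
    assert (tmp_path / "trace.csv").exists()
    assert (tmp_path / "trace_header.json").exists()
    assert "trees" in paths
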