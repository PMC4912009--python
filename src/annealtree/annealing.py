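"""Canonical simulated annealing on the homoplasy index.

The engine performs Metropolis sampling over tree space: at each temperature
``T`` it attempts ``n`` rearrangement moves (NNI and SPR strictly
alternating), accepting a candidate with probability ``min(1, exp(-dHI/T))``
where ``dHI`` is the change in homoplasy index.  Because ``HI = 1 - cK/L``,
the exponent equals ``cK (1/L_current - 1/L_candidate) / T``, so the
alignment's minimum length ``K`` plays the role of the Boltzmann constant.

Every ``l`` moves the working HI is recorded; completed temperature blocks
therefore carry ``n/l`` cost samples from which specific heat is later
estimated.  The temperature then decreases — linearly by a constant ``m``
(the default, for even sampling of all temperature ranges) or geometrically
by a factor ``alpha``.  The run terminates when the schedule reaches its
floor, when a move budget is exhausted, or when the system freezes: a fixed
number of consecutive temperature decrements without improvement of the best
HI seen.

No hill-climbing refinement is run after freezing and no archive of equally
parsimonious trees is kept; the engine is deliberately the bare Metropolis
form so that its thermodynamic record is uncontaminated.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parsimony import ScoringContext, fitch_length, homoplasy_index
from .rearrangement import nni_neighbor, spr_neighbor, alternating_proposer
from .tree_model import Topology, random_topology, write_newick

__all__ = [
    "Schedule",
    "AnnealConfig",
    "TemperatureBlock",
    "RunTrace",
    "acceptance_probability",
    "anneal",
    "acceptance_rate_curve",
    "save_trace",
]


@dataclass(frozen=True)
class Schedule:
    """Cooling schedule.

    kind
        ``linear`` (T decreases by ``m``; stops at/below ``t_floor``),
        ``geometric`` (T multiplied by ``alpha``; never reaches 0) or
        ``constant`` (single temperature; needs a move budget or freezing to
        terminate).
    """

    kind: str = "linear"
    t0: float = 2e-3
    m: float = 1e-7
    alpha: float = 0.99
    t_floor: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("linear", "geometric", "constant"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.t0 <= 0:
            raise ValueError("initial temperature must be positive")
        if self.kind == "linear" and self.m <= 0:
            raise ValueError("linear decrement m must be positive")
        if self.kind == "geometric" and not (0 < self.alpha < 1):
            raise ValueError("geometric ratio alpha must be in (0, 1)")

    @property
    def floor(self) -> float:
        if self.t_floor is not None:
            return self.t_floor
        return self.m if self.kind == "linear" else 0.0

    def next_temperature(self, T: float) -> float:
        if self.kind == "linear":
            return T - self.m
        if self.kind == "geometric":
            return T * self.alpha
        return T  # constant


@dataclass(frozen=True)
class AnnealConfig:
    """Run parameters.

    ``n`` moves are attempted per temperature (default 2000) with the working
    HI stored every ``l`` moves (default 10).  Working topologies are stored
    every ``l_tree`` moves (default 100) but only in blocks whose temperature
    crosses one of ``sample_tree_temperatures`` (fixed prospectively, before
    the run).  ``freeze_window`` consecutive decrements without a new best HI
    terminate the run.  ``proposer`` is ``alternate`` in production;
    ``nni``/``spr`` single-kernel modes exist for diagnostics.
    """

    schedule: Schedule = field(default_factory=Schedule)
    n: int = 2000
    l: int = 10
    l_tree: int = 100
    freeze_window: Optional[int] = 50
    total_move_budget: Optional[int] = None
    seed: int = 0
    proposer: str = "alternate"
    sample_tree_temperatures: tuple[float, ...] = ()
    record_decisions: bool = False

    def __post_init__(self):
        if self.n <= 0 or self.l <= 0 or self.l_tree <= 0:
            raise ValueError("n, l and l_tree must be positive")
        if self.n % self.l != 0:
            raise ValueError("l must divide n")
        if self.n % self.l_tree != 0:
            raise ValueError("l_tree must divide n")
        if self.freeze_window is not None and self.freeze_window <= 0:
            raise ValueError("freeze_window must be positive or None")
        if self.proposer not in ("alternate", "nni", "spr"):
            raise ValueError(f"unknown proposer {self.proposer!r}")
        if self.schedule.kind == "constant" and self.total_move_budget is None \
                and self.freeze_window is None:
            raise ValueError("a constant schedule needs a move budget or freezing")


@dataclass
class TemperatureBlock:
    T: float
    hi_samples: np.ndarray
    accepted_count: int
    proposed_count: int
    nni_count: int
    spr_count: int
    topologies: list[Topology] = field(default_factory=list)


@dataclass
class RunTrace:
    alignment_id: str
    config: AnnealConfig
    initial_topology: Topology
    blocks: list[TemperatureBlock]
    final_topology: Topology
    best_hi: float
    best_length: int
    best_topology: Topology
    termination: str  # frozen | floor | budget
    decisions: Optional[np.ndarray] = None

    def hi_frame(self) -> pd.DataFrame:
        """Long-format (block_index, T, sample_index, HI)."""
        recs = []
        for b_idx, blk in enumerate(self.blocks):
            for s_idx, hi in enumerate(blk.hi_samples):
                recs.append((b_idx, blk.T, s_idx, hi))
        return pd.DataFrame(recs, columns=["block_index", "T", "sample_index", "HI"])


def acceptance_probability(delta_hi: float, T: float) -> float:
    """Metropolis rule: ``min(1, exp(-delta_hi / T))``; step function at T = 0."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if T == 0.0:
        return 1.0 if delta_hi < 0 else 0.0
    if delta_hi <= 0:
        return 1.0
    return math.exp(-delta_hi / T)


def _propose(mode: str, t: Topology, move_index: int, rng):
    if mode == "alternate":
        return alternating_proposer(t, move_index, rng)
    if mode == "nni":
        return nni_neighbor(t, rng)
    return spr_neighbor(t, rng)


def anneal(ctx: ScoringContext, cfg: AnnealConfig, start: Topology | None = None) -> RunTrace:
    """Run one annealing search and return its full per-temperature trace."""
    if ctx.n_taxa < 4:
        raise ValueError("tree search requires at least 4 taxa")
    rng = np.random.default_rng(cfg.seed)
    sched = cfg.schedule
    if start is not None:
        cur = start.copy()
    else:
        cur = random_topology(ctx.n_taxa, rng)
    initial = cur.copy()
    L_cur = fitch_length(cur, ctx)
    hi_cur = homoplasy_index(L_cur, ctx)
    best_hi, best_L, best_top = hi_cur, L_cur, cur.copy()

    tree_temps = sorted(cfg.sample_tree_temperatures, reverse=True)
    tt_ptr = 0
    eps = 1e-15

    blocks: list[TemperatureBlock] = []
    decisions: list[int] = []
    move_index = 0
    proposals_total = 0
    no_improve = 0
    T = sched.t0
    termination = None
    n, l, l_tree = cfg.n, cfg.l, cfg.l_tree
    budget = cfg.total_move_budget
    exp = math.exp
    uniform = rng.random

    while termination is None:
        sample_trees = False
        while tt_ptr < len(tree_temps) and T <= tree_temps[tt_ptr] + eps:
            sample_trees = True
            tt_ptr += 1
        hi_samples = np.empty(n // l)
        accepted = nni_c = spr_c = 0
        topo_samples: list[Topology] = []
        best_before = best_hi
        i = 0
        while i < n:
            prop = _propose(cfg.proposer, cur, move_index, rng)
            move_index += 1
            proposals_total += 1
            i += 1
            if prop.kind == "NNI":
                nni_c += 1
            else:
                spr_c += 1
            L_new = fitch_length(prop.topology, ctx)
            hi_new = homoplasy_index(L_new, ctx)
            delta = hi_new - hi_cur
            if delta <= 0:
                accept = True
            else:
                accept = uniform() < exp(-delta / T)
            if accept:
                cur = prop.topology
                L_cur, hi_cur = L_new, hi_new
                accepted += 1
                if hi_cur < best_hi:
                    best_hi, best_L = hi_cur, L_cur
                    best_top = cur.copy()
            if cfg.record_decisions:
                decisions.append(1 if accept else 0)
            if i % l == 0:
                hi_samples[i // l - 1] = hi_cur
            if sample_trees and i % l_tree == 0:
                topo_samples.append(cur.copy())
            if budget is not None and proposals_total >= budget:
                termination = "budget"
                break
        blocks.append(TemperatureBlock(
            T=T,
            hi_samples=hi_samples[: i // l].copy(),
            accepted_count=accepted,
            proposed_count=i,
            nni_count=nni_c,
            spr_count=spr_c,
            topologies=topo_samples,
        ))
        if termination is not None:
            break
        if best_hi < best_before:
            no_improve = 0
        else:
            no_improve += 1
        if cfg.freeze_window is not None and no_improve >= cfg.freeze_window:
            termination = "frozen"
            break
        T_next = sched.next_temperature(T)
        if sched.kind != "constant" and T_next <= sched.floor:
            termination = "floor"
            break
        T = T_next

    return RunTrace(
        alignment_id=ctx.name,
        config=cfg,
        initial_topology=initial,
        blocks=blocks,
        final_topology=cur,
        best_hi=best_hi,
        best_length=best_L,
        best_topology=best_top,
        termination=termination,
        decisions=np.asarray(decisions, dtype=np.uint8) if cfg.record_decisions else None,
    )


def acceptance_rate_curve(
    ctx: ScoringContext,
    topologies: Sequence[Topology],
    temperatures: Sequence[float],
    n_proposals: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo mean acceptance probability at each temperature.

    Proposals are drawn (alternating NNI/SPR) from the fixed states supplied;
    the same proposal set is evaluated at every temperature, so the returned
    curve is exactly non-decreasing in T.
    """
    rng = np.random.default_rng(seed)
    deltas: list[float] = []
    for t in topologies:
        L0 = fitch_length(t, ctx)
        hi0 = homoplasy_index(L0, ctx)
        for j in range(n_proposals):
            prop = alternating_proposer(t, j, rng)
            hi1 = homoplasy_index(fitch_length(prop.topology, ctx), ctx)
            deltas.append(hi1 - hi0)
    d = np.asarray(deltas)
    out = np.empty(len(temperatures))
    for k, T in enumerate(temperatures):
        out[k] = np.mean([acceptance_probability(x, T) for x in d])
    return out


# ---------------------------------------------------------------------------
# serialisation: CSV of samples + JSON header + newick stream of sampled trees
# ---------------------------------------------------------------------------

def _config_dict(cfg: AnnealConfig) -> dict:
    d = asdict(cfg)
    d["schedule"] = asdict(cfg.schedule)
    return d


def save_trace(trace: RunTrace, out_dir, taxa: Sequence[str] | None = None,
               prefix: str = "trace") -> dict:
    """Write ``<prefix>.csv``, ``<prefix>_header.json`` and, if any topologies
    were sampled, ``<prefix>_trees.tsv`` (block_index, T, newick per line).

    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    csv_path = os.path.join(out_dir, f"{prefix}.csv")
    trace.hi_frame().to_csv(csv_path, index=False)
    paths["csv"] = csv_path
    header = {
        "alignment_id": trace.alignment_id,
        "config": _config_dict(trace.config),
        "termination": trace.termination,
        "best_hi": trace.best_hi,
        "best_length": trace.best_length,
        "n_blocks": len(trace.blocks),
        "taxa": list(taxa) if taxa is not None else None,
        "best_topology": write_newick(trace.best_topology, taxa),
        "final_topology": write_newick(trace.final_topology, taxa),
    }
    hdr_path = os.path.join(out_dir, f"{prefix}_header.json")
    with open(hdr_path, "w") as fh:
        json.dump(header, fh, indent=2)
    paths["header"] = hdr_path
    if any(blk.topologies for blk in trace.blocks):
        trees_path = os.path.join(out_dir, f"{prefix}_trees.tsv")
        with open(trees_path, "w") as fh:
            for b_idx, blk in enumerate(trace.blocks):
                for top in blk.topologies:
                    fh.write(f"{b_idx}\t{blk.T:.10g}\t{write_newick(top, taxa)}\n")
        paths["trees"] = trees_path
    return paths
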