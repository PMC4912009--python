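# Methods

## The optimisation problem

Given a nucleotide multiple alignment over `n` taxa, maximum parsimony seeks
the unrooted binary topology of minimum tree length `L` — the smallest number
of substitutions that can explain the alignment on that topology, computed by
Fitch's post-order dynamic programme (state-set intersection where non-empty,
otherwise union plus one change). To compare across data sets the cost is
normalised: with `K` the sum over columns of each column's tree-independent
minimum change count, the consistency index is `CI = K/L` and the search
minimises the homoplasy index

    HI = 1 − K/L,  HI ∈ [0, 1).

`K ≤ L` for every topology, so `HI ≥ 0`; the degenerate constant-data case
`L = 0` is defined as `CI = 1, HI = 0`.

## The annealing engine

The search is the bare Metropolis form of simulated annealing:

* start from a random topology (stepwise addition: attach each taxon to a
  uniformly chosen edge of the growing tree);
* propose candidates by nearest-neighbour interchange (NNI) and subtree
  pruning-regrafting (SPR) in strict alternation, NNI first. NNI picks a
  uniform internal edge and one of its two alternative arrangements; SPR
  picks a uniform edge and side, prunes, and regrafts onto a uniformly chosen
  edge of the remaining tree, excluding the single merged edge that would
  re-create the source topology (null moves would waste the move budget);
* accept a candidate with probability `min(1, exp(−ΔHI/T))`. Because
  `HI = 1 − K/L`, the exponent is `K(1/L_cur − 1/L_cand)/T`: the data bound
  `K` plays the role of the Boltzmann constant, and may be scaled by a free
  multiplier `c` without touching the data;
* attempt `n` moves per temperature (default 2000), recording the working
  HI every `l` moves (default 10), then cool — linearly by `m` (default
  1e-7, for even sampling of all temperature ranges) or geometrically by
  `alpha` (default 0.99);
* terminate at the schedule floor, on an optional total move budget, or when
  *frozen*: `freeze_window` (default 50) consecutive decrements without
  improving the best HI seen.

Cost-neutral moves (`ΔHI = 0`) are always accepted, so plateaus are
traversed. No hill-climbing refinement runs after freezing and no archive of
equally parsimonious trees is kept — the trace is pure Metropolis sampling.
One RNG stream drives each run; replicate `i` of a batch uses
`base_seed + i`, so no two runs share a seed and whole batches are
reproducible byte-for-byte.

## Thermodynamic instrumentation

Each completed temperature block yields the specific heat

    C(T) = Var(HI samples; ddof=1) / T²,

one (T, C) point per block. Peaks of the profile mark phase transitions:
the temperature range where the search stops wandering among search-space
regions and becomes trapped in one. Peak detection applies a moving-average
smooth (window 5 points) and keeps local maxima whose prominence is at least
0.25 of the global smoothed maximum; the top two by magnitude are reported,
and the profile is classified *double* when they are at least 3 smoothed
points apart, else *single* (*none* for flat profiles). The window and
prominence fraction are free parameters with no canonical values; both are
exposed on the CLI, and raw local maxima beyond the top two are retained for
diagnostics. At most two peaks are classified because one and two are the
observed regimes for this problem class. The critical temperature of a
replicate batch is the mean over replicates of the largest peak's
temperature.

Convergence is exposed by sampling the working topology every `l_tree`
moves (default 100) at 20 linearly spaced temperatures fixed prospectively
between T0 and the schedule floor, then computing per temperature the strict
consensus of the sampled trees, its resolution (fraction of the `n−3`
possible splits retained) and the mean pairwise Robinson–Foulds distance.
Below the critical temperature the sampled trees converge and resolution
rises sharply.

## Experiments

* **Replicated profiling** (`run_replicates`): independent seeded runs on one
  alignment; per-run profiles and peak reports; summary of T_c and C_max.
* **K-scaling** (`k_scaling_experiment`): the batch repeated with the
  Boltzmann multiplier `c` set per factor. The whole temperature grid (T0,
  decrement, floor) is scaled by `c` as well: then, with shared seeds, every
  acceptance decision is identical across arms — the exponent
  `cK·Δ(1/L)/(cT)` is invariant — so T_c scales by exactly `c`. Scaling only
  T0 without the grid would break point-for-point correspondence of blocks.
* **Initial-temperature benchmark** (`benchmark_initial_temperatures`): arms
  start at `T1 < T2 < T3` with `T2` the estimated critical temperature and
  `T3 = 2·T2 − T1`, under geometric cooling. If no move budget is supplied it
  is estimated as the mean proposal count of preliminary freezing runs from
  `T3`; the arms then run with freezing disabled so every arm consumes the
  identical budget and differences in final length reflect T0 alone. A
  warning is raised if the budget leaves a T3 arm above `T2`.

## Synthetic data

`evolve_alignment` evolves a root sequence (uniform base composition by
default) over a known topology; along each branch every site substitutes
independently with probability `p` to one of the three other bases — an
equal-rates, Jukes–Cantor-like process applied as a per-branch probability
rather than a rate. `p` tunes homoplasy: near 0 the optimal tree's CI → 1;
by `p = 0.5` substantial homoplasy accumulates; `p < 0.75` is enforced (the
saturation fixed point). This emulates what the search needs from real
alignments — tree signal plus controllable conflict — but not rate
heterogeneity across sites, non-uniform base composition, indels, or
alignment error; passing tests therefore demonstrate correct behaviour of
the *search and its instrumentation*, not biological accuracy on real data.
Gap and ambiguity handling is exercised by hand-written fixtures instead.
`toy_fixtures` ships three tiny matrices (a clean quartet, a clean 6-taxon
caterpillar, a 6-taxon conflict with tied optima) whose optimal lengths and
topologies are certified by exhaustive enumeration at call time, never
hard-coded.

## Numerical and convention choices

* IUPAC ambiguity codes map to their base sets; `-` and `?` map to full
  ambiguity `{A,C,G,T}` (the classical Fitch treatment), not a fifth state.
* The per-column minimum for `K` counts only unavoidably present bases
  (those some taxon holds as a single-base state set): `max(count, 1) − 1`.
  For columns consisting entirely of partial ambiguities (e.g. R vs Y) this
  undercounts the true resolution minimum, but it preserves `K ≤ L`, which is
  what the HI normalisation requires, and is exact whenever at least the
  represented bases occur unambiguously.
* Variance uses the `ddof=1` estimator; immaterial at 200 samples per block
  but fixed for reproducibility. Constant samples return exactly `C = 0`.
* Scoring is full-tree per proposal (no incremental Fitch caching);
  site-pattern compression plus a compiled kernel supply the needed speed,
  and parsimony-uninformative patterns (every taxon a single base, at most
  one base occurring twice or more) contribute a precomputed
  tree-independent constant.
* Acceptance draws a uniform variate only for uphill proposals; downhill and
  neutral moves consume no randomness beyond the proposal itself. This keeps
  RNG consumption identical across K-scaling arms.
* SPR re-draws the pruned edge when no eligible regraft edge exists (only
  possible at very small n); every returned proposal counts once toward the
  move budget.
* Display rooting on a non-monophyletic outgroup falls back to the edge
  separating the most outgroup taxa, smallest side first, ties broken by the
  lexicographically lowest split — deterministic, and never used in scoring.

## Problem sizes used by the tests and the acceptance script

Full-scale runs (m = 1e-7, i.e. ~20,000 temperatures) take hours per run;
the package's own experiments run at desk scale, which preserves profile
shape:

* optimum recovery: the certified 6-taxon fixture, T0 = 2e-3, m = 1e-5,
  n = 2000, 20 seeds;
* profiling/convergence: one 16-taxon × 500-site alignment (p = 0.05),
  T0 = 2e-2, m = 1e-4, n = 2000, 5 seeds, trees sampled at 20 temperatures;
* K-scaling: 8 taxa × 300 sites (p = 0.1), factors {1, 2}, 20 replicates,
  T0 = 2e-2, m = 2e-4, n = 500;
* size trend: 8/16/24/32 taxa × 300 sites (p = 0.05), 5 replicates each,
  same schedule as K-scaling.

The synthetic alignments here have critical temperatures near 1e-2, so
profiling starts from T0 = 2e-2 (T0 is matched to the peak position, with
2e-3, 1e-2 and 2e-2 the standard choices). Profiling runs disable freezing:
at desk-scale decrements 50 unimproved decrements span half the temperature
range and would truncate the profile while the search is still hot, whereas
at m = 1e-7 the same window is a negligible sliver. Freezing remains the
default for optimisation-style runs and the benchmark's preliminary budget
estimation.

## Known limitations

* Random starts by stepwise addition are not uniform over topologies for
  n > 4 (uniformity is not required; it is the conventional random start).
* The alternating NNI/SPR kernel is not guaranteed symmetric, so no exact
  stationary-distribution claim is made for it; the Metropolis sanity test
  uses the NNI-only mode, whose kernel is symmetric.
* The peak classifier's smoothing window and prominence threshold are
  operational choices; very close double transitions may classify as single.
* `exhaustive_search` is capped at 9 taxa ((2n−5)!! growth).
* No likelihood scoring, no TBR, no adaptive/reheating schedules.
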