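import json

import numpy as np
import pandas as pd
import pytest

from annealtree.alignment_io import write_phylip
from annealtree.annealing import AnnealConfig, Schedule
from annealtree.experiments import (BenchmarkDesign, ReplicateDesign,
                                    benchmark_initial_temperatures,
                                    k_scaling_experiment, run_replicates)
from annealtree.synthetic_data import SimulationParams, evolve_alignment


@pytest.fixture(scope="module")
def small_aln():
    aln, _ = evolve_alignment(SimulationParams(8, 150, p=0.08, seed=77, name="syn8b"))
    return aln


FAST_CFG = AnnealConfig(schedule=Schedule(kind="linear", t0=2e-2, m=4e-4),
                        n=200, l=10, freeze_window=None)


def test_replicates_distinct_seeds_and_determinism(small_aln):
    design = ReplicateDesign(alignment=small_aln, config=FAST_CFG,
                             n_replicates=4, base_seed=5)
    assert len(set(design.seeds())) == 4
    r1 = run_replicates(design)
    r2 = run_replicates(design)
    assert len(r1.table) == 4
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_replicates_summary_exposes_tc_and_magnitude(small_aln):
    design = ReplicateDesign(alignment=small_aln, config=FAST_CFG,
                             n_replicates=3, base_seed=1)
    r = run_replicates(design)
    assert {"T_c", "C_max", "best_length", "termination"} <= set(r.table.columns)
    assert r.table["T_c"].notna().all()
    assert (r.table["C_max"] > 0).all()


def test_ksweep_identity_arm_matches_plain_replicates(small_aln):
    r_plain = run_replicates(ReplicateDesign(alignment=small_aln, config=FAST_CFG,
                                             n_replicates=3, base_seed=2))
    r_sweep = k_scaling_experiment(small_aln, factors=(1.0,), n_replicates=3,
                                   config=FAST_CFG, base_seed=2)
    assert np.allclose(r_plain.table["T_c"], r_sweep.table["T_c"])
    assert list(r_plain.table["best_length"]) == list(r_sweep.table["best_length"])


def test_ksweep_small_factor_lowers_tc(small_aln):
    r = k_scaling_experiment(small_aln, factors=(0.1, 1.0), n_replicates=3,
                             config=FAST_CFG, base_seed=3)
    tb = r.table
    low = tb[tb.arm == "c=0.1"]["T_c"].mean()
    ref = tb[tb.arm == "c=1"]["T_c"].mean()
    assert low < ref


def test_benchmark_arithmetic_and_budget_parity(small_aln):
    design = BenchmarkDesign(t1=1e-4, t2=5e-4, n_replicates=2, budget=3000,
                             n=500, l=10, base_seed=0, alpha=0.9)
    assert design.t3 == pytest.approx(9e-4)
    with pytest.warns(RuntimeWarning):
        result = benchmark_initial_temperatures(small_aln, design)
    spent = [sum(b.proposed_count for b in tr.blocks) for tr in result.traces]
    assert set(spent) == {3000}
    assert set(result.table["arm"]) == {"T1=0.0001", "T2=0.0005", "T3=0.0009"}


def test_benchmark_estimates_budget_from_prelim(small_aln):
    design = BenchmarkDesign(t1=2e-3, t2=8e-3, n_replicates=1, n_prelim=1,
                             n=200, l=10, alpha=0.5, freeze_window=5,
                             base_seed=0)
    result = benchmark_initial_temperatures(small_aln, design)
    budget = result.table.attrs["budget"]
    assert budget > 0
    spent = [sum(b.proposed_count for b in tr.blocks) for tr in result.traces]
    assert set(spent) == {budget}


def test_cli_simulate_profile_consensus_pipeline(tmp_path):
    from annealtree.cli import main

    sim_dir = tmp_path / "sim"
    assert main(["simulate", "--taxa", "8", "--sites", "120", "--p", "0.08",
                 "--seed", "4", "--out-dir", str(sim_dir)]) == 0
    assert (sim_dir / "aln.phy").exists()
    assert (sim_dir / "truth.nwk").exists()
    assert (sim_dir / "manifest.json").exists()

    run_dir = tmp_path / "run"
    assert main(["profile", str(sim_dir / "aln.phy"), "--t0", "2e-2", "--m",
                 "4e-4", "--n", "200", "--freeze-window", "1000000",
                 "--seed", "1", "--sample-trees", "--plot",
                 "--out-dir", str(run_dir)]) == 0
    for name in ("trace.csv", "trace_header.json", "trace_trees.tsv",
                 "profile.csv", "peaks.json", "profile.png", "manifest.json"):
        assert (run_dir / name).exists(), name
    peaks = json.loads((run_dir / "peaks.json").read_text())
    assert "classification" in peaks

    cons_dir = tmp_path / "cons"
    assert main(["consensus", str(run_dir), "--out-dir", str(cons_dir)]) == 0
    assert (cons_dir / "consensus.csv").exists()
    assert (cons_dir / "consensus_trees.nwk").exists()


def test_cli_usage_error_exits_nonzero(tmp_path):
    from annealtree.cli import main

    bad = tmp_path / "missing.phy"
    assert main(["profile", str(bad)]) != 0
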