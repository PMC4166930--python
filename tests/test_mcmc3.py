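"""MH kernel, heating, swaps, the nonblocking scheduler and the run API."""

import math

import numpy as np
import pandas as pd
import pytest

from bayestree.mcmc3 import (DiscreteChain, RunConfig,
                             SwapScheduler, attempt_swap, heat, run,
                             run_coupled, write_topologies_nexus,
                             write_trace_tsv)
from bayestree.msa_io import compress_patterns
from bayestree.postprocess import read_topologies_nexus, split_frequencies
from bayestree.simdata import generate_bushy_tree, simulate_alignment
from bayestree.evolmodel import build_model, discretize_gamma


def test_heat_closed_forms():
    assert heat(0, 0.1) == 1.0
    assert heat(1, 0.1) == pytest.approx(1 / 1.1)
    betas = [heat(i, 0.2) for i in range(5)]
    assert all(b > c for b, c in zip(betas, betas[1:]))
    with pytest.raises(ValueError):
        heat(-1, 0.1)


def test_discrete_chain_matches_enumerated_target():
    chain = DiscreteChain([0.2, 0.3, 0.5], rng=np.random.default_rng(1))
    n = 100000
    occ = np.zeros(3)
    for _ in range(n):
        chain.step()
        occ[chain.state] += 1
    occ /= n
    for k, p in enumerate([0.2, 0.3, 0.5]):
        # inflate the binomial SE for autocorrelation (conservative factor)
        se = math.sqrt(p * (1 - p) / n) * 3
        assert abs(occ[k] - p) < 3 * se


def test_flat_target_always_accepts():
    chain = DiscreteChain([1, 1, 1], rng=np.random.default_rng(0))
    assert all(chain.step() for _ in range(200))


def test_heated_discrete_chain_flattens():
    cold = DiscreteChain([0.05, 0.95], rng=np.random.default_rng(2))
    hot = DiscreteChain([0.05, 0.95], beta=0.1, rng=np.random.default_rng(3))
    occ_c = occ_h = 0
    for _ in range(30000):
        cold.step()
        hot.step()
        occ_c += cold.state == 0
        occ_h += hot.state == 0
    assert occ_h > occ_c * 2      # heat raises minority-state occupancy


def test_swap_identical_states_always_accepted():
    rng = np.random.default_rng(0)
    a = DiscreteChain([0.2, 0.8], beta=1.0, state=1)
    b = DiscreteChain([0.2, 0.8], beta=0.5, state=1)
    assert all(attempt_swap(a, b, rng) for _ in range(100))


def test_swap_equal_heats_always_accepted():
    rng = np.random.default_rng(0)
    a = DiscreteChain([0.2, 0.8], beta=0.7, state=0)
    b = DiscreteChain([0.2, 0.8], beta=0.7, state=1)
    assert attempt_swap(a, b, rng)


def test_swap_generation_mismatch_is_error():
    a = DiscreteChain([0.5, 0.5])
    b = DiscreteChain([0.5, 0.5])
    b.generation = 5
    with pytest.raises(RuntimeError, match="scheduler"):
        attempt_swap(a, b, np.random.default_rng(0))


def test_coupled_cold_chain_unbiased():
    """Coupling must not change the cold chain's stationary law."""
    target = [0.2, 0.3, 0.5]
    chains = [DiscreteChain(target, beta=heat(i, 0.5),
                            rng=np.random.default_rng(10 + i))
              for i in range(2)]
    sched = SwapScheduler(2, rng=np.random.default_rng(9))
    occ = np.zeros(3)

    def tally(cold):
        occ[cold.state] += 1

    run_coupled(chains, 50000, sched, sample_every=1, on_sample=tally,
                audit_every=0)
    occ /= occ.sum()
    for k, p in enumerate(target):
        se = math.sqrt(p * (1 - p) / 50000) * 3
        assert abs(occ[k] - p) < 3 * se


def test_scheduler_liveness_and_ticket_uniqueness():
    sched = SwapScheduler(4, interval=1, lag=3, rng=np.random.default_rng(0))
    chains = [DiscreteChain([0.3, 0.7], beta=heat(i, 0.2),
                            rng=np.random.default_rng(20 + i))
              for i in range(4)]
    for gen in range(1, 50):
        for c in chains:
            c.step()
        sched.tick(gen)
        busy = sched._pending_members()
        # a chain holds at most one pending ticket
        members = [i for t in sched.tickets for i in t.pair]
        assert len(members) == len(set(members))
        # every chain advanced this generation regardless of tickets
        assert all(c.generation == gen for c in chains)
        sched.resolve(chains, gen)
    assert sum(sched.pair_attempts.values()) > 0


def test_lag_zero_two_chains_is_blocking_sequence():
    """interval 1, lag 0, two chains: a swap is attempted every single
    generation — the classic synchronous MC³ schedule."""
    sched = SwapScheduler(2, interval=1, lag=0, rng=np.random.default_rng(0))
    chains = [DiscreteChain([0.4, 0.6], beta=heat(i, 0.3),
                            rng=np.random.default_rng(30 + i))
              for i in range(2)]
    for gen in range(1, 101):
        for c in chains:
            c.step()
        sched.tick(gen)
        done = sched.resolve(chains, gen)
        assert len(done) == 1 and done[0].issued_generation == gen


def test_swap_acceptance_decreases_with_heat_separation():
    rates = []
    for delta in (0.05, 0.4, 2.0):
        chains = [DiscreteChain([0.02, 0.98], beta=heat(i, delta),
                                rng=np.random.default_rng(40 + i))
                  for i in range(2)]
        sched = SwapScheduler(2, rng=np.random.default_rng(50))
        run_coupled(chains, 20000, sched, audit_every=0)
        rates.append(sched.pair_accepts.get((0, 1), 0)
                     / sched.pair_attempts[(0, 1)])
    assert rates[0] > rates[1] > rates[2]


def _tiny_dataset(seed=5):
    tree = generate_bushy_tree(6, 0.3, 0.05, seed=seed)
    model = build_model("DNA")
    gamma = discretize_gamma(0.7)
    aln, _ = simulate_alignment(tree, model, gamma, 300, seed=seed + 1)
    return tree, compress_patterns(aln)


def test_zero_generations_trace_is_initial_state():
    _, pm = _tiny_dataset()
    config = RunConfig(n_runs=1, n_generations=0, sample_every=10, seed=3)
    res = run(config, pm)[0]
    assert len(res.trace) == 1
    assert res.trace["generation"].iloc[0] == 0
    assert len(res.topologies) == 1


def test_run_is_bitwise_deterministic():
    _, pm = _tiny_dataset()
    config = RunConfig(n_runs=2, n_generations=400, sample_every=20, seed=11)
    a = run(config, pm)
    b = run(config, pm)
    for ra, rb in zip(a, b):
        pd.testing.assert_frame_equal(ra.trace, rb.trace)
        assert ra.topologies == rb.topologies
    # independent runs differ (decorrelated streams)
    assert not a[0].trace.equals(a[1].trace)


def test_run_recovers_strong_signal_topology():
    tree = generate_bushy_tree(6, 0.3, 0.1, seed=21)
    aln, _ = simulate_alignment(tree, build_model("DNA"),
                                discretize_gamma(0.7), 2000, seed=22)
    pm = compress_patterns(aln)
    config = RunConfig(n_runs=1, n_generations=3000, sample_every=20, seed=7)
    res = run(config, pm)[0]
    table = split_frequencies(res.topologies, burnin_fraction=0.33,
                              taxon_names=pm.taxon_names)
    for s in tree.splits():
        assert table.frequency(s) > 0.9


def test_audit_passes_during_run():
    """Cached vs recomputed log-likelihood agreement is verified in-run."""
    _, pm = _tiny_dataset(seed=8)
    config = RunConfig(n_runs=1, n_generations=1000, sample_every=100,
                       seed=2, audit_every=200)
    run(config, pm)     # any divergence raises


def test_coupled_phylo_run_smoke():
    _, pm = _tiny_dataset(seed=9)
    config = RunConfig(n_runs=1, n_coupled_chains=2, n_generations=300,
                       sample_every=50, seed=13)
    res = run(config, pm)[0]
    assert res.scheduler is not None
    assert sum(res.scheduler.pair_attempts.values()) > 0
    assert res.chains[0].beta == 1.0


def test_output_files_round_trip(tmp_path):
    _, pm = _tiny_dataset(seed=10)
    config = RunConfig(n_runs=1, n_generations=200, sample_every=50, seed=4)
    res = run(config, pm)[0]
    tsv = tmp_path / "params.tsv"
    nex = tmp_path / "topo.nex"
    write_trace_tsv(res.trace, tsv)
    write_topologies_nexus(res.topologies, pm.taxon_names, nex)
    back = pd.read_csv(tsv, sep="\t")
    assert list(back.columns) == list(res.trace.columns)
    newicks, names = read_topologies_nexus(nex)
    assert names == pm.taxon_names
    assert len(newicks) == len(res.topologies)
    t0 = split_frequencies(newicks, taxon_names=names)
    t1 = split_frequencies(res.topologies, taxon_names=names)
    assert t0.frequencies() == t1.frequencies()
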