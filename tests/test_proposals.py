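"""Move-set correctness: closed forms, reversibility, walk symmetry,
autotuning."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import dirichlet as dirichlet_dist

from bayestree.evolmodel import LinkageMap, ModelState, PriorConfig
from bayestree.mcmc3 import PhyloChain
from bayestree.proposals import (BranchMultiplier, ESpr,
                                 NodeSlider, Proposal,
                                 StNni, _dirichlet_step, autotune,
                                 default_move_set, nni, nni_swap)
from bayestree.tree import Tree, parse_newick


class _Bare:
    """Minimal chain stand-in for tree-only proposals."""

    def __init__(self, tree):
        self.tree = tree
        self.sample_model_params = True


def test_branch_multiplier_hastings_is_log_multiplier(rng):
    tree = parse_newick("((a:0.2,b:0.2):0.1,c:0.2,d:0.2);")
    mv = BranchMultiplier(theta=2.0)
    for _ in range(50):
        before = {e: tree.branch_length(e) for e in tree.edges}
        rec = mv.propose(_Bare(tree), rng)
        eid = rec.info["edge"]
        m = tree.branch_length(eid) / before[eid]
        assert rec.log_hastings == pytest.approx(math.log(m), abs=1e-12)
        assert abs(rec.log_hastings) <= 1.0 + 1e-12      # |θ(u-½)| ≤ θ/2
        rec.undo()
        assert {e: tree.branch_length(e) for e in tree.edges} == before


def test_node_slider_preserves_total_and_is_symmetric(rng):
    tree = parse_newick("((a:0.2,b:0.3):0.1,c:0.2,d:0.2);")
    mv = NodeSlider()
    total = tree.tree_length()
    for _ in range(30):
        rec = mv.propose(_Bare(tree), rng)
        assert rec.log_hastings == 0.0
        assert tree.tree_length() == pytest.approx(total)
        assert all(v[0] > 0 for v in tree.lengths.values())


def test_dirichlet_step_density_pair_matches_scipy_oracle(rng):
    for _ in range(20):
        x = rng.dirichlet(np.ones(4) * 2)
        prop, logh = _dirichlet_step(x, 200.0, rng)
        fwd = dirichlet_dist.logpdf(prop, np.maximum(200.0 * x, 1e-6))
        rev = dirichlet_dist.logpdf(x, np.maximum(200.0 * prop, 1e-6))
        assert logh == pytest.approx(rev - fwd, abs=1e-10)
        assert prop.sum() == pytest.approx(1.0)
        assert np.all(prop > 0)


def test_dirichlet_huge_concentration_degenerates(rng):
    x = np.full(4, 0.25)
    prop, logh = _dirichlet_step(x, 1e8, rng)
    assert np.max(np.abs(prop - x)) < 1e-3
    assert abs(logh) < 1e-2


def test_nni_is_involution(rng):
    tree = Tree.from_random_joins([f"t{i}" for i in range(8)], rng, 0.1)
    for eid in tree.internal_edge_ids():
        for variant in (0, 1):
            before = tree.splits()
            a, b = nni(tree, eid, variant)
            assert tree.splits() != before
            nni_swap(tree, eid, a, b)       # same swap undoes itself
            assert tree.splits() == before


def test_stnni_proposal_space_on_four_taxa(rng):
    names = list("abcd")
    start = parse_newick("((a:1,b:1):1,c:1,d:1);", names)
    mv = StNni()
    seen = Counter()
    for _ in range(4000):
        t = start.copy()
        mv.propose(_Bare(t), rng)
        seen[next(iter(t.splits()))] += 1
    # the two alternative topologies, each with probability ~1/2
    assert len(seen) == 2
    lo, hi = sorted(seen.values())
    se = 3 * math.sqrt(0.25 * 4000)
    assert abs(hi - lo) < 2 * se


def test_espr_stop_prob_one_is_single_step(rng):
    tree = Tree.from_random_joins([f"t{i}" for i in range(8)], rng, 0.1)
    mv = ESpr(stop_prob=1.0)
    for _ in range(50):
        rec = mv.propose(_Bare(tree), rng)
        assert rec.info.get("null") or rec.info["path_len"] == 1
        rec.undo()


def test_espr_undo_restores_bitwise(rng):
    tree = Tree.from_random_joins([f"t{i}" for i in range(10)], rng, 0.1)
    mv = ESpr(stop_prob=0.4)
    for _ in range(100):
        adjacency = {v: dict(nb) for v, nb in tree.adjacency.items()}
        lengths = {e: v.copy() for e, v in tree.lengths.items()}
        rec = mv.propose(_Bare(tree), rng)
        rec.undo()
        assert tree.adjacency == adjacency
        assert all(np.array_equal(tree.lengths[e], lengths[e])
                   for e in lengths)


def test_espr_uniform_stationarity_on_five_taxa(rng):
    """Always-accepting eSPR leaves the uniform distribution over the 15
    five-taxon topologies stationary (the space is vertex-transitive and
    the walk law is label-equivariant)."""
    tree = Tree.from_random_joins(list("abcde"), rng, 0.2)
    mv = ESpr(stop_prob=0.5)
    counts = Counter()
    n = 30000
    for _ in range(n):
        mv.propose(_Bare(tree), rng)
        counts[frozenset(tree.splits())] += 1
    assert len(counts) == 15
    p = 1 / 15
    se = math.sqrt(p * (1 - p) / n)
    for c in counts.values():
        assert abs(c / n - p) < 4 * se


def test_moves_keep_state_in_support(rng):
    """No proposal may produce nonpositive branch lengths or off-simplex
    parameters."""
    ms = ModelState(["DNA"], LinkageMap.linked(1))
    chain = PhyloChain(Tree.from_random_joins(list("abcdef"), rng, 0.1),
                       ms, None, PriorConfig(), rng=rng)
    for _ in range(3000):
        chain.step()
        assert all(v[0] > 0 for v in chain.tree.lengths.values())
        for pi in chain.model_state.freq_groups:
            assert np.all(pi > 0) and pi.sum() == pytest.approx(1.0)
        for r in chain.model_state.exch_groups:
            assert np.all(r > 0) and r.sum() == pytest.approx(1.0)
        assert chain.model_state.alpha_groups[0] > 0


def test_autotune_fixed_point_and_monotone():
    p = Proposal(theta=1.0)
    autotune(p, p.target_acceptance)
    assert p.theta == 1.0
    thetas = []
    for _ in range(50):
        autotune(p, 1.0)
        thetas.append(p.theta)
    assert all(b >= a for a, b in zip(thetas, thetas[1:]))
    assert thetas[-1] == p.bounds[1]


def test_autotune_converges_on_gaussian_target(rng):
    """Tuned random-walk acceptance settles into a sensible band on a
    standard normal target."""
    theta = 20.0     # start far too wide
    x = 0.0
    acc_rate = 0.0
    p = Proposal(theta=theta, bounds=(1e-3, 1e3))
    for window in range(50):
        acc = 0
        for _ in range(100):
            prop = x + p.theta * (rng.random() - 0.5)
            if math.log(rng.random()) < -(prop ** 2 - x ** 2) / 2:
                x = prop
                acc += 1
        acc_rate = acc / 100
        autotune(p, acc_rate)
    assert 0.15 <= acc_rate <= 0.40


def test_default_move_set_weights_positive():
    moves = default_move_set()
    assert len(moves) == 7
    assert all(m.weight > 0 for m in moves)
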