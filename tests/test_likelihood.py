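"""Pruning likelihood: closed forms, exhaustive oracle, memory modes, SEV,
cache invalidation and numerical scaling."""

import io
import itertools
import math

import numpy as np
import pytest

from bayestree.evolmodel import build_model, discretize_gamma
from bayestree.likelihood import (LikelihoodEngine, LikelihoodError,
                                  compute_loglik, compute_loglik_sev,
                                  memory_budget)
from bayestree.msa_io import Alignment, compress_patterns, read_alignment
from bayestree.tree import Tree, parse_newick

from conftest import random_alignment, random_instance


def brute_force_loglik(tree, aln, model, gamma):
    """Exhaustive sum over all internal-state assignments per site and
    category — the independent oracle for the pruning recursion."""
    root = tree.eval_root()
    order = tree.postorder(root)
    internals = [n for n, _ in order if n >= tree.n_taxa]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for site in range(aln.n_sites):
        lik = 0.0
        for cat in range(gamma.n_categories):
            P = {e: model.transition_probs(tree.lengths[e][0] * gamma.rates[cat])
                 for e in tree.edges}
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, assign))
                for i in range(tree.n_taxa):
                    st[i] = idx[aln.matrix[i][site]]
                pr = model.frequencies[st[root]]
                stack = [(root, None)]
                while stack:
                    n, par = stack.pop()
                    for u in tree.adjacency[n]:
                        if u == par:
                            continue
                        pr *= P[tree.adjacency[n][u]][st[n], st[u]]
                        stack.append((u, n))
                lik += pr * gamma.probs[cat]
        total += math.log(lik)
    return total


def test_two_taxa_zero_branch_limit():
    aln = read_alignment(io.StringIO(">a\nACGT\n>b\nACGT\n"), "fasta")
    t = Tree(["a", "b"])
    t.add_edge(0, 1, 1e-12)
    ll = compute_loglik(t, build_model("DNA"), discretize_gamma(1, 1),
                        compress_patterns(aln))
    assert ll == pytest.approx(4 * math.log(0.25), abs=1e-6)


def test_two_taxa_jc_closed_form():
    aln = read_alignment(io.StringIO(">a\nACGT\n>b\nACGA\n"), "fasta")
    t = Tree(["a", "b"])
    dist = 0.3
    t.add_edge(0, 1, dist)
    ll = compute_loglik(t, build_model("DNA"), discretize_gamma(1, 1),
                        compress_patterns(aln))
    same = 0.25 * (0.25 + 0.75 * math.exp(-4 * dist / 3))
    diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * dist / 3))
    assert ll == pytest.approx(3 * math.log(same) + math.log(diff), abs=1e-10)


def test_pruning_matches_exhaustive_enumeration(rng):
    for _ in range(3):
        tree, model, gamma, pm, aln = random_instance(rng, 5, 20)
        assert compute_loglik(tree, model, gamma, pm) == pytest.approx(
            brute_force_loglik(tree, aln, model, gamma), abs=1e-8)


def test_sev_equals_plain_engine_no_missing(rng):
    tree, model, gamma, pm, _ = random_instance(rng, 6, 40)
    plain = LikelihoodEngine(pm, models=model, gammas=gamma)
    sev = LikelihoodEngine(pm, models=model, gammas=gamma, use_sev=True)
    assert sev.loglik(tree) == pytest.approx(plain.loglik(tree), abs=1e-10)
    assert sev.clv_entries_stored == plain.count_stored_entries()


def test_fully_missing_taxon_equals_allones_oracle(rng):
    """A taxon of pure gaps contributes all-ones partials; the SEV engine
    must agree with the naive engine treating '?' as the full state set."""
    names = [f"t{i}" for i in range(6)]
    mat = rng.choice(list("ACGT"), size=(6, 30))
    mat[2, :] = "?"
    aln = Alignment(names, mat)
    tree = Tree.from_random_joins(names, rng, 0.2)
    model = build_model("DNA")
    gamma = discretize_gamma(0.8)
    pm = compress_patterns(aln)
    naive = compute_loglik(tree, model, gamma, pm)
    assert compute_loglik_sev(tree, model, gamma, pm) == pytest.approx(
        naive, abs=1e-10)
    # equals the likelihood with the taxon dropped and its branch summed out
    keep = [0, 1, 3, 4, 5]
    sub = Alignment([names[i] for i in keep], mat[keep])
    # build the induced 5-taxon tree via newick surgery: drop t2
    import dendropy
    dt = dendropy.Tree.get(data=tree.newick(precision=12), schema="newick")
    dt.retain_taxa_with_labels([names[i] for i in keep])
    sub_tree = parse_newick(dt.as_string(schema="newick",
                                         suppress_rooting=True).strip(),
                            sub.taxon_names)
    ll_sub = compute_loglik(sub_tree, model, gamma, compress_patterns(sub))
    assert naive == pytest.approx(ll_sub, abs=1e-8)


def test_sev_reduces_storage_under_block_missing(rng):
    from bayestree.simdata import (apply_missingness, generate_bushy_tree,
                                   simulate_alignment)
    tree = generate_bushy_tree(16, 0.3, 0.03, seed=rng)
    model = build_model("DNA")
    gamma = discretize_gamma(0.5)
    aln, parts = simulate_alignment(tree, [model] * 4, gamma, 50, seed=rng)
    aln = apply_missingness(aln, 0.75, block_structured=True, seed=rng,
                            partitions=parts)
    pm = compress_patterns(aln, parts)
    plain = LikelihoodEngine(pm, models=model, gammas=gamma)
    sev = LikelihoodEngine(pm, models=model, gammas=gamma, use_sev=True)
    assert sev.loglik(tree) == pytest.approx(plain.loglik(tree), abs=1e-10)
    assert sev.clv_entries_stored < plain.count_stored_entries()


@pytest.mark.parametrize("mode,bound", [
    ("economy", lambda n: math.ceil((n - 2) / 2)),
    ("minimal", lambda n: 2 * math.ceil(math.log2(n)) + 2),
])
def test_memory_modes_identical_and_bounded(rng, mode, bound):
    for n_taxa in (8, 16, 64):
        tree, model, gamma, pm, _ = random_instance(rng, n_taxa, 30)
        full = LikelihoodEngine(pm, models=model, gammas=gamma)
        ll_full = full.loglik(tree)
        eng = LikelihoodEngine(pm, models=model, gammas=gamma, mem_mode=mode)
        assert eng.loglik(tree) == ll_full          # bitwise
        assert eng.peak_resident_slots <= max(bound(n_taxa), 3)


def test_budget_floor_error(rng):
    with pytest.raises(ValueError, match="unknown memory mode"):
        memory_budget("tiny", 16)
    tree, model, gamma, pm, _ = random_instance(rng, 16, 20)
    eng = LikelihoodEngine(pm, models=model, gammas=gamma, mem_mode="minimal")
    eng.budget = 1          # below the single-pass floor
    with pytest.raises(LikelihoodError, match="floor|budget"):
        eng.loglik(tree)


def test_full_mode_caches_between_evaluations(rng):
    tree, model, gamma, pm, _ = random_instance(rng, 8, 25)
    eng = LikelihoodEngine(pm, models=model, gammas=gamma)
    ll = eng.loglik(tree)
    before = eng.recompute_events
    assert eng.loglik(tree) == ll
    assert eng.recompute_events == before     # zero recomputation events


def test_pendant_branch_edit_recomputes_only_path(rng):
    tree, model, gamma, pm, _ = random_instance(rng, 8, 25)
    eng = LikelihoodEngine(pm, models=model, gammas=gamma)
    eng.loglik(tree)
    # edit the pendant branch of the taxon farthest from the root
    root = tree.eval_root()
    depth = {root: 0}
    parent = {}
    for node, children in reversed(tree.postorder(root)):
        for c, e in children:
            depth[c] = depth[node] + 1
            parent[c] = node
    leaf = max((v for v in depth if v < tree.n_taxa), key=lambda v: depth[v])
    eid = tree.adjacency[leaf][parent[leaf]]
    tree.set_branch_length(eid, tree.branch_length(eid) * 1.7)
    before = eng.recompute_events
    ll_inc = eng.loglik(tree)
    path_len = depth[leaf]                    # ancestors incl. root
    assert eng.recompute_events - before == path_len
    fresh = LikelihoodEngine(pm, models=model, gammas=gamma)
    assert ll_inc == pytest.approx(fresh.loglik(tree), abs=1e-10)


def test_nni_then_loglik_matches_fresh_engine(rng):
    from bayestree.proposals import nni
    tree, model, gamma, pm, _ = random_instance(rng, 8, 25)
    eng = LikelihoodEngine(pm, models=model, gammas=gamma)
    eng.loglik(tree)
    eid = tree.internal_edge_ids()[0]
    nni(tree, eid, 0)
    fresh = LikelihoodEngine(pm, models=model, gammas=gamma)
    assert eng.loglik(tree) == pytest.approx(fresh.loglik(tree), abs=1e-10)


def test_invalidate_unknown_node_errors(rng):
    tree, model, gamma, pm, _ = random_instance(rng, 6, 10)
    eng = LikelihoodEngine(pm, models=model, gammas=gamma)
    eng.loglik(tree)
    with pytest.raises(KeyError):
        eng.invalidate(999)


def test_traversal_rerooting_invariance(rng):
    """Pulley principle: the likelihood does not depend on where the
    serialization (and hence the evaluation root) sits."""
    import dendropy
    tree, model, gamma, pm, _ = random_instance(rng, 8, 30)
    ll = compute_loglik(tree, model, gamma, pm)
    tns = dendropy.TaxonNamespace(tree.taxon_names)
    dt = dendropy.Tree.get(data=tree.newick(precision=14), schema="newick",
                           taxon_namespace=tns)
    for node in list(dt.preorder_internal_node_iter())[1:3]:
        dt.reroot_at_node(node)
        alt = parse_newick(dt.as_string(schema="newick").strip(),
                           tree.taxon_names)
        assert compute_loglik(alt, model, gamma, pm) == pytest.approx(
            ll, abs=1e-8)


def test_deep_caterpillar_with_tiny_branches_is_finite():
    n = 1000
    names = [f"s{i}" for i in range(n)]
    t = Tree(names)
    spine = t.new_node()
    t.add_edge(spine, 0, 1e-9)
    t.add_edge(spine, 1, 1e-9)
    prev = spine
    for leaf in range(2, n - 1):
        nd = t.new_node()
        t.add_edge(prev, nd, 1e-9)
        t.add_edge(nd, leaf, 1e-9)
        prev = nd
    t.add_edge(prev, n - 1, 1e-9)
    rng = np.random.default_rng(3)
    aln = random_alignment(n, 8, rng)
    ll = compute_loglik(t, build_model("DNA"), discretize_gamma(1, 1),
                        compress_patterns(aln))
    assert np.isfinite(ll)
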