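"""Consensus, ASDSF, sample statistics, RF distance and MDS embedding."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from bayestree.postprocess import (SplitTable, asdsf, consensus_tree,
                                   effective_sample_size, mds_embed,
                                   rf_distance, sample_stats,
                                   split_frequencies, splits_compatible)
from bayestree.tree import Tree, parse_newick


def random_trees(rng, n_taxa, n_trees, names=None):
    names = names or [f"t{i}" for i in range(n_taxa)]
    return [Tree.from_random_joins(names, rng, 0.1) for _ in range(n_trees)]


def test_identical_samples_all_splits_at_one(rng):
    t = Tree.from_random_joins([f"t{i}" for i in range(8)], rng, 0.1)
    table = split_frequencies([t.copy() for _ in range(10)])
    assert set(table.frequencies().values()) == {1.0}
    assert len(table.counts) == t.n_taxa - 3


def test_split_counting_example(rng):
    names = list("abcde")
    a = parse_newick("(((a:1,b:1):1,c:1):1,d:1,e:1);", names)
    b = parse_newick("(((a:1,c:1):1,b:1):1,d:1,e:1);", names)
    samples = [a] * 6 + [b] * 4
    table = split_frequencies(samples)
    ab_split = 0b11000      # side without taxon a: {c,d,e}? counts mask below
    # split {a,b} canonicalized to the complement side {c,d,e} = 0b11100
    assert table.frequency(0b11100) == pytest.approx(0.6)


def test_frequencies_match_dendropy_oracle(rng):
    names = [f"t{i}" for i in range(7)]
    trees = random_trees(rng, 7, 20, names)
    table = split_frequencies(trees)
    tns = dendropy.TaxonNamespace(names)
    dlist = dendropy.TreeList(
        [dendropy.Tree.get(data=t.newick(), schema="newick",
                           taxon_namespace=tns) for t in trees],
        taxon_namespace=tns)
    full = (1 << 7) - 1
    counter = {}
    for dt in dlist:
        dt.encode_bipartitions()
        for b in dt.bipartition_encoding:
            mask = int(b.split_bitmask)
            if mask & 1:
                mask ^= full
            nb = bin(mask).count("1")
            if 1 < nb < 6:
                counter[mask] = counter.get(mask, 0) + 1
    assert {s: c / 20 for s, c in counter.items()} == table.frequencies()


def test_burnin_discarded(rng):
    names = list("abcdef")
    t1 = Tree.from_random_joins(names, rng, 0.1)
    t2 = Tree.from_random_joins(names, rng, 0.1)
    samples = [t1] * 5 + [t2] * 5
    table = split_frequencies(samples, burnin_fraction=0.5)
    for s in t2.splits():
        assert table.frequency(s) == 1.0


def test_taxon_mismatch_rejected(rng):
    a = Tree.from_random_joins(list("abcd"), rng)
    b = Tree.from_random_joins(list("abce"), rng)
    with pytest.raises(ValueError, match="mismatch"):
        split_frequencies([a, b])


def test_consensus_identical_samples(rng):
    t = Tree.from_random_joins([f"t{i}" for i in range(8)], rng, 0.1)
    table = split_frequencies([t.copy() for _ in range(5)])
    cons, support = consensus_tree(table)
    assert cons.splits() == t.splits()
    assert set(support.values()) == {1.0}


def test_consensus_two_thirds_example(rng):
    names = list("abcde")
    a = parse_newick("(((a:1,b:1):1,c:1):1,d:1,e:1);", names)
    b = parse_newick("(((a:1,c:1):1,b:1):1,d:1,e:1);", names)
    table = split_frequencies([a, a, b])
    cons, support = consensus_tree(table, threshold=0.5)
    ab = 0b11100        # complement of {a,b}
    assert ab in cons.splits()
    assert support[ab] == pytest.approx(2 / 3)


def test_majority_consensus_compatibility_property(rng):
    """Majority-rule output splits are pairwise compatible and include
    every split above the threshold."""
    for _ in range(200):
        n = int(rng.integers(5, 10))
        trees = random_trees(rng, n, int(rng.integers(3, 12)))
        table = split_frequencies(trees)
        cons, support = consensus_tree(table, extended=bool(rng.integers(2)))
        splits = list(cons.splits())
        for s, f in table.frequencies().items():
            if f > 0.5:
                assert s in splits
        for x, y in itertools.combinations(splits, 2):
            assert splits_compatible(x, y, n)


def test_asdsf_identical_runs_is_zero(rng):
    trees = random_trees(rng, 6, 10)
    t = split_frequencies(trees)
    assert asdsf([t, t]) == 0.0


def test_asdsf_hand_example():
    """Two runs, one qualifying split at frequencies 0.4 / 0.6:
    population SD = 0.1, so ASDSF = 0.1."""
    names = list("abcd")
    a = SplitTable(names, n_samples=10, counts={0b1100: 4})
    b = SplitTable(names, n_samples=10, counts={0b1100: 6})
    assert asdsf([a, b]) == pytest.approx(0.1)


def test_asdsf_min_freq_filter():
    names = list("abcd")
    a = SplitTable(names, n_samples=100, counts={0b1100: 5})
    b = SplitTable(names, n_samples=100, counts={0b1100: 5})
    assert asdsf([a, b], min_freq=0.1) == 0.0     # below threshold everywhere
    with pytest.raises(ValueError):
        asdsf([a])


def test_asdsf_decreases_with_more_sampling(rng):
    """Two samplers of the same tree distribution disagree less as the
    sample grows."""
    names = [f"t{i}" for i in range(6)]

    def run_pair(n):
        t1 = split_frequencies(random_trees(rng, 6, n, names))
        t2 = split_frequencies(random_trees(rng, 6, n, names))
        return asdsf([t1, t2])

    small = np.mean([run_pair(20) for _ in range(5)])
    large = np.mean([run_pair(400) for _ in range(5)])
    assert large < small


def test_ess_iid_normal(rng):
    x = rng.normal(size=10000)
    ess, flag = effective_sample_size(x)
    assert not flag
    assert abs(ess - 10000) / 10000 < 0.15


def test_ess_ar1_closed_form(rng):
    rho, n = 0.5, 20000
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(size=n) * math.sqrt(1 - rho ** 2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    ess, _ = effective_sample_size(x)
    assert abs(ess - n / 3) / (n / 3) < 0.2


def test_sample_stats_constant_trace():
    trace = pd.DataFrame({"a": [2.5] * 50})
    out = sample_stats(trace)
    assert out.loc["a", "mean"] == 2.5
    assert out.loc["a", "ci_upper"] - out.loc["a", "ci_lower"] == 0.0
    assert out.loc["a", "degenerate"]
    assert out.loc["a", "ess"] == 50


def test_rf_examples(rng):
    names = list("abcd")
    t1 = parse_newick("((a:1,b:1):1,c:1,d:1);", names)
    t2 = parse_newick("((a:1,c:1):1,b:1,d:1);", names)
    assert rf_distance(t1, t1.copy()) == 0
    assert rf_distance(t1, t2) == 2


def test_rf_symmetry_and_bounds(rng):
    for _ in range(200):
        n = int(rng.integers(4, 16))
        a, b = random_trees(rng, n, 2)
        d = rf_distance(a, b)
        assert d == rf_distance(b, a)
        assert 0 <= d <= 2 * (n - 3)


def test_rf_matches_dendropy(rng):
    names = [f"t{i}" for i in range(10)]
    tns = dendropy.TaxonNamespace(names)
    for _ in range(20):
        a, b = random_trees(rng, 10, 2, names)
        da = dendropy.Tree.get(data=a.newick(), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(data=b.newick(), schema="newick",
                               taxon_namespace=tns)
        expect = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert rf_distance(a, b) == expect


def test_mds_equilateral_triangle():
    D = np.ones((3, 3)) - np.eye(3)
    X = mds_embed(D)
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(X[i] - X[j]) == pytest.approx(1.0, abs=1e-6)


def test_mds_zero_matrix_jitters_duplicates():
    D = np.zeros((6, 6))
    X = mds_embed(D, jitter_seed=4)
    radius = 1e-3
    for i in range(6):
        for j in range(i + 1, 6):
            d = np.linalg.norm(X[i] - X[j])
            assert d <= 2 * radius        # adjacent
            assert d > 0                  # but not identical


def test_mds_recovers_plane_up_to_rigid_motion(rng):
    pts = rng.normal(size=(12, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    X = mds_embed(D)
    # Procrustes: align X to pts and measure residual
    Xc = X - X.mean(0)
    Pc = pts - pts.mean(0)
    U, _, Vt = np.linalg.svd(Xc.T @ Pc)
    R = U @ Vt
    assert np.max(np.abs(Xc @ R - Pc)) < 1e-6


def test_mds_rejects_asymmetric():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        mds_embed(D)
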