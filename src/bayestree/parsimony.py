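"""Fitch parsimony and randomized stepwise-addition starting trees.

The MCMC runs are seeded by reasonable (non-random) starting topologies:
taxa are inserted in a seeded random order, each on the branch that
minimizes the Fitch parsimony score of the grown tree.  Fitch state sets
are bitmasks, so ambiguity codes and missing data ('-'/'?', encoded as the
full state set) cost nothing extra.
"""

from __future__ import annotations

import numpy as np

from .msa_io import Alignment, PatternMatrix, compress_patterns
from .tree import Tree

__all__ = ["fitch_score", "stepwise_addition_tree"]


def fitch_score(tree: Tree, pattern_matrix: PatternMatrix) -> int:
    """Minimum number of state changes on *tree* under Fitch parsimony,
    summed over weighted patterns and partitions.

    The tree is rooted at an arbitrary internal node for the sweep; the
    score is root-invariant.  State sets at a multifurcating evaluation
    root are folded pairwise, which equals rooting along any incident edge.
    """
    if pattern_matrix.n_taxa != tree.n_taxa:
        raise ValueError("taxon count mismatch between tree and patterns")
    if tree.n_taxa == 2:
        total = 0
        for part in pattern_matrix.partitions:
            empty = (part.codes[0] & part.codes[1]) == 0
            total += int(part.weights[empty].sum())
        return total
    return _fitch_score_partial(tree, pattern_matrix)


def stepwise_addition_tree(data: Alignment | PatternMatrix,
                           seed: int | np.random.Generator = 0,
                           branch_length: float = 0.1) -> Tree:
    """Greedy parsimony starting tree by randomized stepwise addition.

    Taxa are inserted in a seeded random order; each insertion picks the
    branch minimizing the Fitch score of the resulting tree, ties broken by
    the lowest branch index.  Branch lengths are initialized to a constant
    (default 0.1); MCMC burn-in refines them.
    """
    pm = compress_patterns(data) if isinstance(data, Alignment) else data
    n = pm.n_taxa
    if n < 4:
        raise ValueError("stepwise addition needs at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(n)]

    tree = Tree(pm.taxon_names)
    hub = tree.new_node()
    for leaf in order[:3]:
        tree.add_edge(hub, leaf, branch_length)

    for taxon in order[3:]:
        best = None
        for eid in tree.edge_ids():
            a, b = tree.edges[eid]
            length = tree.lengths[eid].copy()
            tree.remove_edge(eid)
            mid = tree.new_node()
            e1 = tree.add_edge(a, mid, length)
            e2 = tree.add_edge(mid, b, length)
            e3 = tree.add_edge(mid, taxon, branch_length)
            score = _fitch_score_partial(tree, pm)
            if best is None or score < best[0]:
                best = (score, eid)
            # undo insertion
            tree.remove_edge(e1)
            tree.remove_edge(e2)
            tree.remove_edge(e3)
            tree.remove_node(mid)
            restored = tree.add_edge(a, b, length)
            # keep the original edge id so branch indices stay stable
            tree.adjacency[a][b] = eid
            tree.adjacency[b][a] = eid
            tree.edges[eid] = tree.edges.pop(restored)
            tree.lengths[eid] = tree.lengths.pop(restored)
        _, eid = best
        a, b = tree.edges[eid]
        length = tree.lengths[eid].copy()
        tree.remove_edge(eid)
        mid = tree.new_node()
        tree.add_edge(a, mid, length)
        tree.add_edge(mid, b, length)
        tree.add_edge(mid, taxon, branch_length)
    tree.validate()
    return tree


def _fitch_score_partial(tree: Tree, pm: PatternMatrix) -> int:
    """Fitch score of a tree over a subset of the taxa (during stepwise
    addition the tree does not yet contain every leaf)."""
    # pick an internal node adjacent to a present leaf as evaluation root
    attached = next(v for v in tree.adjacency
                    if v < tree.n_taxa and tree.adjacency[v])
    root = next(iter(tree.adjacency[attached]))
    total = 0
    for part in pm.partitions:
        masks: dict[int, np.ndarray] = {}
        score = 0
        weights = part.weights
        for node, children in tree.postorder(root):
            if node < tree.n_taxa:
                masks[node] = part.codes[node]
                continue
            acc = None
            for c, _ in children:
                m = masks.pop(c)
                if acc is None:
                    acc = m
                    continue
                inter = acc & m
                empty = inter == 0
                acc = np.where(empty, acc | m, inter)
                score += int(weights[empty].sum())
            masks[node] = acc
        total += score
    return total
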