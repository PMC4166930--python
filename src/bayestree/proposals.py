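"""MCMC proposal distributions over trees and model parameters.

Every move mutates the chain's state in place and returns a
:class:`MoveRecord` carrying the log Hastings ratio and an undo callable
that restores the state bit-for-bit on rejection.  Topological moves:
stochastic NNI and extended SPR (a non-backtracking random walk of the
regraft point with per-step stop probability; the Hastings ratio is
computed exactly from the forward and reverse walk probabilities, and is 0
in the interior where the walk law is symmetric).  Parameter moves:
multiplier proposals for branch lengths and the Γ shape, a node slider
redistributing length between adjacent branches, and Dirichlet proposals
centered at the current frequencies/exchangeabilities.

Each proposal carries a tuning parameter θ updated by ``autotune`` toward a
target acceptance rate; tuning is frozen after burn-in so the sampled chain
stays Markovian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import dirichlet as dirichlet_dist

from .tree import Tree

__all__ = [
    "MoveRecord", "Proposal", "BranchMultiplier", "NodeSlider",
    "FrequencyDirichlet", "ExchangeabilityDirichlet", "AlphaMultiplier",
    "StNni", "ESpr", "autotune", "default_move_set", "nni", "spr_prune",
    "spr_regraft",
]

_EPS = 1e-6


@dataclass
class MoveRecord:
    name: str
    log_hastings: float
    undo: Callable[[], None]
    changes_tree: bool = False
    changes_model: bool = False
    info: dict = field(default_factory=dict)


@dataclass
class Proposal:
    """Base class: a weighted, tunable move."""

    weight: float = 1.0
    theta: float = 1.0
    bounds: tuple[float, float] = (1e-4, 1e4)
    target_acceptance: float = 0.25
    name: str = "proposal"
    # +1 for step-size-like θ (bigger θ -> lower acceptance), -1 for
    # concentration-like θ (bigger θ -> higher acceptance)
    tune_direction: int = 1
    # acceptance bookkeeping for autotuning
    attempts: int = 0
    accepts: int = 0

    def propose(self, chain, rng: np.random.Generator) -> MoveRecord:
        raise NotImplementedError

    def applicable(self, chain) -> bool:
        return True


# ------------------------------------------------------- tree length moves

class BranchMultiplier(Proposal):
    """b' = b·exp(θ(u−½)); log Hastings = log multiplier."""

    def __init__(self, weight=30.0, theta=2 * math.log(1.6)):
        super().__init__(weight=weight, theta=theta, name="branch_multiplier")

    def propose(self, chain, rng):
        tree: Tree = chain.tree
        eids = tree.edge_ids()
        eid = eids[rng.integers(len(eids))]
        group = int(rng.integers(tree.n_bl_groups))
        old = tree.lengths[eid][group]
        m = math.exp(self.theta * (rng.random() - 0.5))
        tree.lengths[eid][group] = old * m

        def undo():
            tree.lengths[eid][group] = old

        return MoveRecord(self.name, math.log(m), undo, changes_tree=True,
                          info={"edge": eid, "group": group})


class NodeSlider(Proposal):
    """Redistribute the total length of two adjacent branches uniformly;
    symmetric, Hastings 0."""

    def __init__(self, weight=10.0):
        super().__init__(weight=weight, name="node_slider")

    def applicable(self, chain):
        return chain.tree.n_taxa >= 3

    def propose(self, chain, rng):
        tree: Tree = chain.tree
        internals = sorted(tree.internal_nodes)
        v = internals[rng.integers(len(internals))]
        nbrs = sorted(tree.adjacency[v])
        i, j = rng.choice(len(nbrs), size=2, replace=False)
        e1 = tree.adjacency[v][nbrs[int(i)]]
        e2 = tree.adjacency[v][nbrs[int(j)]]
        group = int(rng.integers(tree.n_bl_groups))
        b1, b2 = tree.lengths[e1][group], tree.lengths[e2][group]
        total = b1 + b2
        new1 = max(total * rng.random(), 1e-12)
        tree.lengths[e1][group] = new1
        tree.lengths[e2][group] = max(total - new1, 1e-12)

        def undo():
            tree.lengths[e1][group] = b1
            tree.lengths[e2][group] = b2

        return MoveRecord(self.name, 0.0, undo, changes_tree=True)


# --------------------------------------------------------- parameter moves

def _dirichlet_step(current: np.ndarray, concentration: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Draw x' ~ Dir(c·x) and return (x', log Hastings) with exact forward
    and reverse densities.  Components are floored at 1e-6 and renormalized
    to keep both densities proper."""
    alpha_fwd = np.maximum(concentration * current, _EPS)
    prop = rng.dirichlet(alpha_fwd)
    prop = np.maximum(prop, _EPS)
    prop = prop / prop.sum()
    alpha_rev = np.maximum(concentration * prop, _EPS)
    log_fwd = dirichlet_dist.logpdf(prop, alpha_fwd)
    log_rev = dirichlet_dist.logpdf(current, alpha_rev)
    return prop, float(log_rev - log_fwd)


class FrequencyDirichlet(Proposal):
    def __init__(self, weight=2.0, theta=300.0):
        super().__init__(weight=weight, theta=theta, bounds=(1.0, 1e6),
                         name="frequency_dirichlet", tune_direction=-1)

    def applicable(self, chain):
        return chain.sample_model_params

    def propose(self, chain, rng):
        ms = chain.model_state
        g = int(rng.integers(len(ms.freq_groups)))
        old = ms.freq_groups[g]
        old_cache = dict(ms._model_cache)
        prop, logh = _dirichlet_step(old, self.theta, rng)
        ms.set_frequencies(g, prop)

        def undo():
            ms.freq_groups[g] = old
            ms._model_cache = old_cache

        return MoveRecord(self.name, logh, undo, changes_model=True)


class ExchangeabilityDirichlet(Proposal):
    def __init__(self, weight=2.0, theta=300.0):
        super().__init__(weight=weight, theta=theta, bounds=(1.0, 1e6),
                         name="exchangeability_dirichlet", tune_direction=-1)

    def applicable(self, chain):
        return chain.sample_model_params

    def propose(self, chain, rng):
        ms = chain.model_state
        g = int(rng.integers(len(ms.exch_groups)))
        old = ms.exch_groups[g]
        old_cache = dict(ms._model_cache)
        prop, logh = _dirichlet_step(old, self.theta, rng)
        ms.set_exchangeabilities(g, prop)

        def undo():
            ms.exch_groups[g] = old
            ms._model_cache = old_cache

        return MoveRecord(self.name, logh, undo, changes_model=True)


class AlphaMultiplier(Proposal):
    def __init__(self, weight=2.0, theta=1.0):
        super().__init__(weight=weight, theta=theta, name="alpha_multiplier")

    def applicable(self, chain):
        return chain.sample_model_params

    def propose(self, chain, rng):
        ms = chain.model_state
        g = int(rng.integers(len(ms.alpha_groups)))
        old = ms.alpha_groups[g]
        old_gamma = dict(ms._gamma_cache)
        m = math.exp(self.theta * (rng.random() - 0.5))
        ms.set_alpha(g, old * m)

        def undo():
            ms.alpha_groups[g] = old
            ms._gamma_cache = old_gamma

        return MoveRecord(self.name, math.log(m), undo, changes_model=True)


# -------------------------------------------------------- topological moves

def _snapshot(tree: Tree):
    return ({v: dict(nb) for v, nb in tree.adjacency.items()},
            dict(tree.edges),
            {e: v.copy() for e, v in tree.lengths.items()},
            tree._next_node, tree._next_edge)


def _restore(tree: Tree, snap) -> None:
    adjacency, edges, lengths, nn, ne = snap
    tree.adjacency = {v: dict(nb) for v, nb in adjacency.items()}
    tree.edges = dict(edges)
    tree.lengths = {e: v.copy() for e, v in lengths.items()}
    tree._next_node = nn
    tree._next_edge = ne


def _rewire(tree: Tree, eid: int, frm: int, to: int) -> None:
    """Move the *frm* endpoint of edge *eid* to node *to*."""
    x, y = tree.edges[eid]
    other = y if x == frm else x
    del tree.adjacency[frm][other]
    del tree.adjacency[other][frm]
    tree.adjacency[to][other] = eid
    tree.adjacency[other][to] = eid
    tree.edges[eid] = (to, other)


def nni_swap(tree: Tree, eid: int, a: int, b: int) -> None:
    """Swap the subtrees hanging from neighbors *a* and *b* across internal
    edge *eid* (the two must attach to opposite endpoints).  The operation
    is an involution: the same call restores the original topology."""
    u, v = tree.edges[eid]
    if u < tree.n_taxa or v < tree.n_taxa:
        raise ValueError("NNI needs an internal branch")
    if a in tree.adjacency[v] and b in tree.adjacency[u]:
        a, b = b, a
    if a not in tree.adjacency[u] or b not in tree.adjacency[v]:
        raise ValueError("NNI neighbors must attach to opposite edge ends")
    ea = tree.adjacency[u][a]
    eb = tree.adjacency[v][b]
    _rewire(tree, ea, u, v)
    _rewire(tree, eb, v, u)


def nni(tree: Tree, eid: int, variant: int) -> tuple[int, int]:
    """One of the two nearest-neighbor interchanges around internal edge
    *eid* (variant 0 or 1).  Returns the swapped neighbor pair, which can
    be fed back to :func:`nni_swap` to undo the move."""
    u, v = tree.edges[eid]
    if u < tree.n_taxa or v < tree.n_taxa:
        raise ValueError("NNI needs an internal branch")
    a = sorted(x for x in tree.adjacency[u] if x != v)[0]
    b = sorted(x for x in tree.adjacency[v] if x != u)[variant]
    nni_swap(tree, eid, a, b)
    return a, b


class StNni(Proposal):
    """Stochastic NNI: uniform internal branch, one of its two
    rearrangements with probability ½ each; symmetric (Hastings 0)."""

    def __init__(self, weight=5.0):
        super().__init__(weight=weight, name="st_nni")

    def applicable(self, chain):
        return chain.tree.n_taxa >= 4

    def propose(self, chain, rng):
        tree: Tree = chain.tree
        internal = tree.internal_edge_ids()
        eid = internal[rng.integers(len(internal))]
        variant = int(rng.integers(2))
        snap = _snapshot(tree)
        nni(tree, eid, variant)

        def undo():
            _restore(tree, snap)

        return MoveRecord(self.name, 0.0, undo, changes_tree=True,
                          info={"edge": eid, "variant": variant})


def spr_prune(tree: Tree, u: int, v: int) -> tuple[int, int, int]:
    """Prune the subtree hanging from *v* at internal node *u*.

    Removes u's two other edges and joins its remaining neighbors c1, c2 by
    a fresh edge of summed length.  Returns ``(joined_edge, c1, c2)``; the
    pruned unit (u plus the subtree through v) stays connected via the
    retained edge (u, v).
    """
    c1, c2 = sorted(x for x in tree.adjacency[u] if x != v)
    e1 = tree.adjacency[u][c1]
    e2 = tree.adjacency[u][c2]
    joined = tree.lengths[e1] + tree.lengths[e2]
    tree.remove_edge(e1)
    tree.remove_edge(e2)
    e0 = tree.add_edge(c1, c2, joined)
    return e0, c1, c2


def spr_regraft(tree: Tree, u: int, eid: int, split: float) -> None:
    """Regraft the pruned node *u* into edge *eid*, placing the split point
    a fraction *split* of the way from the lower-id endpoint."""
    x, y = sorted(tree.edges[eid])
    total = tree.lengths[eid].copy()
    tree.remove_edge(eid)
    tree.add_edge(x, u, np.maximum(total * split, 1e-12))
    tree.add_edge(u, y, np.maximum(total * (1.0 - split), 1e-12))


def _adjacent_edges(tree: Tree, eid: int) -> list[int]:
    x, y = tree.edges[eid]
    out = [tree.adjacency[x][z] for z in tree.adjacency[x] if tree.adjacency[x][z] != eid]
    out += [tree.adjacency[y][z] for z in tree.adjacency[y] if tree.adjacency[y][z] != eid]
    return sorted(set(out))


class ESpr(Proposal):
    """Extended subtree prune-and-regraft.

    A uniformly chosen subtree is pruned; the regraft edge is found by a
    non-backtracking random walk from the pruning site that extends with
    probability 1−stop_prob per step (a trapped walk regrafts where it
    stands).  With stop_prob = 1 the walk length is one step, the
    NNI-adjacent single-step SPR.  The Hastings ratio combines the exact
    forward/reverse walk probabilities with the uniform length-split
    density of the regraft (and of its reverse rejoin).
    """

    def __init__(self, weight=15.0, stop_prob=0.5):
        super().__init__(weight=weight, name="e_spr")
        if not (0 < stop_prob <= 1):
            raise ValueError("stop_prob must be in (0, 1]")
        self.stop_prob = stop_prob

    def applicable(self, chain):
        return chain.tree.n_taxa >= 4

    def propose(self, chain, rng):
        tree: Tree = chain.tree
        snap = _snapshot(tree)
        # candidate directed edges u -> v with internal tail u
        cands = []
        for eid in tree.edge_ids():
            a, b = tree.edges[eid]
            if a >= tree.n_taxa:
                cands.append((a, b))
            if b >= tree.n_taxa:
                cands.append((b, a))
        u, v = cands[rng.integers(len(cands))]
        e0, c1, c2 = spr_prune(tree, u, v)
        len_e0 = float(tree.lengths[e0][0])

        p = self.stop_prob
        log_fwd = 0.0
        adj0 = _adjacent_edges(tree, e0)
        if not adj0:
            # pruning left a bare cherry: nowhere to walk; null move
            _restore(tree, snap)
            return MoveRecord(self.name, 0.0, lambda: None, changes_tree=False,
                              info={"null": True})
        cur = adj0[rng.integers(len(adj0))]
        log_fwd += -math.log(len(adj0))
        prev = e0
        path = [e0, cur]
        while True:
            shared = set(tree.edges[cur]) & set(tree.edges[prev])
            far = next(x for x in tree.edges[cur] if x not in shared)
            ext = [tree.adjacency[far][z] for z in tree.adjacency[far]
                   if tree.adjacency[far][z] != cur]
            if not ext:
                break                        # trapped: forced stop
            if rng.random() < p:
                log_fwd += math.log(p)
                break
            log_fwd += math.log1p(-p) - math.log(len(ext))
            ext.sort()
            nxt = ext[rng.integers(len(ext))]
            prev, cur = cur, nxt
            path.append(cur)

        # reverse-walk probability along the same edge path
        log_rev = -math.log(len(_adjacent_edges(tree, path[-1])))
        for i in range(len(path) - 2, 0, -1):
            # reverse step from path[i+1] onto path[i] extends through the
            # vertex shared by path[i] and path[i-1]
            shared = set(tree.edges[path[i]]) & set(tree.edges[path[i - 1]])
            vtx = shared.pop()
            ext_n = len(tree.adjacency[vtx]) - 1
            log_rev += math.log1p(-p) - math.log(ext_n)
        # reverse stop at e0: extensions through the far end of e0
        shared = set(tree.edges[e0]) & set(tree.edges[path[1]])
        far0 = next(x for x in tree.edges[e0] if x not in shared)
        ext0 = sum(1 for z in tree.adjacency[far0]
                   if tree.adjacency[far0][z] != e0)
        log_rev += math.log(p) if ext0 > 0 else 0.0

        target = path[-1]
        len_target = float(tree.lengths[target][0])
        split = rng.random()
        spr_regraft(tree, u, target, split)
        # uniform split-position densities: forward 1/len(target), reverse 1/len(e0)
        logh = (log_rev - log_fwd) + (math.log(len_target) - math.log(len_e0))

        def undo():
            _restore(tree, snap)

        return MoveRecord(self.name, logh, undo, changes_tree=True,
                          info={"pruned": u, "target": target, "path_len": len(path) - 1})


# ------------------------------------------------------------------- tuning

def autotune(proposal: Proposal, acceptance_rate: float, delta: float = 1.0) -> Proposal:
    """Scale θ by exp(δ·(acc − target)), clamped to the proposal's bounds.

    Concentration-like proposals (Dirichlet moves) declare
    ``tune_direction = -1`` since for them a larger θ *raises* acceptance.
    """
    lo, hi = proposal.bounds
    proposal.theta = min(max(proposal.theta * math.exp(
        proposal.tune_direction * delta
        * (acceptance_rate - proposal.target_acceptance)), lo), hi)
    return proposal


def default_move_set() -> list[Proposal]:
    """Topology-heavy default menu (weights sum is arbitrary; selection is
    by relative weight)."""
    return [
        StNni(weight=5.0),
        ESpr(weight=15.0, stop_prob=0.5),
        BranchMultiplier(weight=30.0),
        NodeSlider(weight=10.0),
        FrequencyDirichlet(weight=2.0),
        ExchangeabilityDirichlet(weight=2.0),
        AlphaMultiplier(weight=2.0),
    ]
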