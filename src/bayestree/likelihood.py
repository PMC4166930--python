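"""Felsenstein-pruning log-likelihood with caching and memory saving.

The engine evaluates the phylogenetic likelihood of an unrooted tree under
per-partition reversible substitution models with discrete-Γ rate
categories.  Conditional likelihood vectors (CLVs) are stored per internal
node with shape ``(k_categories, n_patterns, n_states)``; per-pattern
scaling counters (powers of 2**256) prevent underflow on deep trees.

Cache validity is signature-based: every stored CLV remembers the child
nodes, branch lengths and model objects it was computed from, so after any
tree or parameter edit exactly the affected CLVs are recomputed — there is
no separate dirty-flag bookkeeping to get out of sync.

Two orthogonal memory-saving techniques are provided:

* bounded-memory recomputation — ``economy`` and ``minimal`` modes cap the
  number of resident CLVs and deterministically evict
  farthest-from-the-evaluation-root first, recomputing on demand;
* a subtree-equality shortcut for missing data (SEV): patterns whose
  content below a node is entirely missing have a constant all-ones CLV
  which is never stored, shrinking memory in proportion to the fraction of
  missing data.

All paths produce numerically identical log-likelihoods (same per-node
summation order); they differ only in what is kept resident.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .evolmodel import GammaRates, ModelState, SubstModel
from .msa_io import PatternMatrix
from .tree import Tree

__all__ = ["LikelihoodEngine", "compute_loglik", "compute_loglik_sev",
           "memory_budget"]

_RESCALE_BITS = 256
_RESCALE_THRESH = 2.0 ** -_RESCALE_BITS
_RESCALE_FACTOR = 2.0 ** _RESCALE_BITS
_LOG_RESCALE = _RESCALE_BITS * math.log(2.0)


class LikelihoodError(ArithmeticError):
    pass


def memory_budget(mode: str, n_taxa: int) -> int:
    """Resident internal-node CLV budget for a memory mode.

    ``full`` keeps all ``n - 2`` internal CLVs, ``economy`` about half, and
    ``minimal`` a logarithmic number (enough for one pruning pass when the
    deeper subtree is always evaluated first)."""
    n_internal = max(n_taxa - 2, 1)
    if mode == "full":
        return n_internal
    if mode == "economy":
        return max(math.ceil(n_internal / 2), 3)
    if mode == "minimal":
        return 2 * math.ceil(math.log2(max(n_taxa, 2))) + 2
    raise ValueError(f"unknown memory mode {mode!r}")


class _Models:
    """Adapter resolving per-partition model/Γ/branch-length group."""

    def __init__(self, pattern_matrix, models, gammas, model_state, bl_groups):
        n_parts = len(pattern_matrix.partitions)
        self.state = model_state
        if model_state is not None:
            self.bl_groups = [int(g) for g in model_state.linkage.branch_lengths]
        else:
            if isinstance(models, SubstModel):
                models = [models] * n_parts
            if isinstance(gammas, GammaRates):
                gammas = [gammas] * n_parts
            self.models = list(models)
            self.gammas = list(gammas)
            self.bl_groups = list(bl_groups) if bl_groups is not None else [0] * n_parts

    def model(self, p: int) -> SubstModel:
        if self.state is not None:
            return self.state.model_for_partition(p)
        return self.models[p]

    def gamma(self, p: int) -> GammaRates:
        if self.state is not None:
            return self.state.gamma_for_partition(p)
        return self.gammas[p]


class LikelihoodEngine:
    """Incremental pruning likelihood over a :class:`PatternMatrix`.

    Parameters may be given either as a sampled :class:`ModelState` (the
    MCMC path) or as explicit per-partition ``models``/``gammas``.
    """

    def __init__(self, pattern_matrix: PatternMatrix,
                 models=None, gammas=None, model_state: ModelState | None = None,
                 bl_groups: Sequence[int] | None = None,
                 mem_mode: str = "full", use_sev: bool = False):
        self.patterns = pattern_matrix
        self.n_taxa = pattern_matrix.n_taxa
        self._models = _Models(pattern_matrix, models, gammas, model_state, bl_groups)
        self.mem_mode = mem_mode
        self.budget = memory_budget(mem_mode, self.n_taxa)
        self.use_sev = use_sev
        self._tips: dict[tuple[int, int], np.ndarray] = {}
        self._store: dict[int, list] = {}      # node -> per-partition (clv, scale)
        self._sigs: dict[int, list] = {}       # node -> per-partition signature
        self._cached_loglik: float | None = None
        self._undo: dict[int, tuple] | None = None
        self._undo_loglik: float | None = None
        # instrumentation
        self.recompute_events = 0
        self.peak_resident_slots = 0
        self.clv_entries_stored = 0

    # ------------------------------------------------------------- utilities

    def set_memory_mode(self, mode: str) -> None:
        budget = memory_budget(mode, self.n_taxa)
        floor = memory_budget("minimal", self.n_taxa)
        if budget < min(floor, self.n_taxa - 2):
            raise ValueError(f"budget {budget} below single-pass floor {floor}")
        self.mem_mode = mode
        self.budget = budget
        self._trim_to_budget(root_depth={}, needed=set())
        self._cached_loglik = None

    def invalidate(self, node_or_edge: int, is_edge: bool = False,
                   tree: Tree | None = None) -> None:
        """Force recomputation of a node's CLV (and, transitively, of every
        CLV on the path to the evaluation root at the next evaluation)."""
        if is_edge:
            if tree is None or node_or_edge not in tree.edges:
                raise KeyError(f"unknown edge {node_or_edge}")
            for end in tree.edges[node_or_edge]:
                self._sigs.pop(end, None)
        else:
            if node_or_edge not in self._sigs:
                raise KeyError(f"unknown node {node_or_edge}")
            del self._sigs[node_or_edge]
        self._cached_loglik = None

    def _tip(self, taxon: int, part: int) -> np.ndarray:
        key = (taxon, part)
        t = self._tips.get(key)
        if t is None:
            t = self.patterns.partitions[part].tip_partials(taxon)
            self._tips[key] = t
        return t

    # ------------------------------------------------------- undo/transaction

    def begin(self) -> None:
        self._undo = {}
        self._undo_loglik = self._cached_loglik

    def rollback(self) -> None:
        if self._undo is None:
            raise RuntimeError("no transaction to roll back")
        for node, (clv, sig) in self._undo.items():
            if clv is None:
                self._store.pop(node, None)
                self._sigs.pop(node, None)
            else:
                self._store[node] = clv
                self._sigs[node] = sig
        self._cached_loglik = self._undo_loglik
        self._undo = None

    def commit(self) -> None:
        self._undo = None

    def _stash(self, node: int) -> None:
        if self._undo is not None and node not in self._undo:
            if node in self._store:
                self._undo[node] = (self._store[node], self._sigs[node])
            else:
                self._undo[node] = (None, None)

    # ------------------------------------------------------------ evaluation

    def loglik(self, tree: Tree) -> float:
        if self.use_sev:
            return self._loglik_sev(tree)
        root = tree.eval_root()
        order = tree.postorder(root)
        n_parts = len(self.patterns.partitions)

        depth = {root: 0}
        for node, children in reversed(order):
            for c, _ in children:
                depth[c] = depth[node] + 1
        heights: dict[int, int] = {}
        for node, children in order:
            heights[node] = 1 + max((heights[c] for c, _ in children), default=0)

        is_clv_node = lambda v: v >= self.n_taxa or v == root
        sigs_now: dict[int, list] = {}
        for node, children in order:
            if not is_clv_node(node):
                continue
            sigs_now[node] = [
                (self._models.model(p), self._models.gamma(p),
                 tuple((c, tree.lengths[e][self._models.bl_groups[p]])
                       for c, e in children))
                for p in range(n_parts)]

        # pass 1: propagate "value changed" flags toward the root
        changed: set[int] = set()
        for node, children in order:
            if not is_clv_node(node):
                continue
            if (self._sigs.get(node) != sigs_now[node]
                    or any(c in changed for c, _ in children)):
                changed.add(node)

        if not changed and root in self._store and self._cached_loglik is not None:
            return self._cached_loglik

        # pass 2: bounded-residency evaluation, deeper subtrees first
        children_of = dict(order)
        needed: set[int] = set()

        def compute(node: int) -> None:
            children = children_of[node]
            self._stash(node)
            per_part = []
            for p in range(n_parts):
                g = self._models.gamma(p)
                model = self._models.model(p)
                bl = self._models.bl_groups[p]
                clv = None
                scale = None
                for c, e in children:
                    t = tree.lengths[e][bl]
                    P = model.transition_probs(t, g.rates)      # (k, s, s)
                    PT = np.ascontiguousarray(P.transpose(0, 2, 1))
                    if c < self.n_taxa:
                        contrib = np.matmul(self._tip(c, p)[None, :, :], PT)
                    else:
                        child_clv, child_scale = self._store[c][p]
                        contrib = np.matmul(child_clv, PT)
                        scale = child_scale if scale is None else scale + child_scale
                    clv = contrib if clv is None else clv * contrib
                if node < self.n_taxa:      # two-taxon case: root is a leaf
                    clv = clv * self._tip(node, p)[None, :, :]
                if scale is None:
                    scale = np.zeros(clv.shape[1], dtype=np.int32)
                # cheap contiguous reduce; the per-pattern max is only
                # needed when some entry actually dipped below threshold
                gmin = float(clv.min())
                if gmin != gmin:
                    raise LikelihoodError(
                        f"non-finite partial likelihood at node {node}, partition {p}")
                if gmin < _RESCALE_THRESH:
                    pmax = clv.max(axis=0).max(axis=1)
                    small = (pmax < _RESCALE_THRESH) & (pmax > 0)
                    if small.any():
                        clv[:, small, :] *= _RESCALE_FACTOR
                        scale = scale + small.astype(np.int32)
                per_part.append((clv, scale))
            self._store[node] = per_part
            self._sigs[node] = sigs_now[node]
            self.recompute_events += 1

        # iterative depth-first "ensure resident and up to date", taller
        # subtrees first so one pruning pass fits a logarithmic budget
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if not expanded:
                needed.add(node)
                if node in self._store and node not in changed:
                    self._track_peak()
                    continue
                internal = sorted(
                    (c for c, _ in children_of[node] if c >= self.n_taxa),
                    key=lambda c: (-heights[c], c))
                stack.append((node, True))
                for c in reversed(internal):
                    stack.append((c, False))
            else:
                compute(node)
                changed.discard(node)
                for c, _ in children_of[node]:
                    needed.discard(c)
                needed.add(node)
                self._trim_to_budget(depth, needed)
                self._track_peak()
        needed.clear()
        self._trim_to_budget(depth, {root})

        total = self._root_reduce(root)
        self._cached_loglik = total
        return total

    def _trim_to_budget(self, root_depth: dict[int, int], needed: set[int]) -> None:
        if len(self._store) <= self.budget:
            return
        evictable = [n for n in self._store if n not in needed]
        # farthest from root first; ties by descending node id
        evictable.sort(key=lambda n: (-root_depth.get(n, 0), -n))
        while len(self._store) > self.budget:
            if not evictable:
                raise LikelihoodError(
                    f"CLV budget {self.budget} below the floor needed for one "
                    f"pruning pass")
            n = evictable.pop(0)
            self._stash(n)
            del self._store[n]
            self._sigs.pop(n, None)

    def _track_peak(self) -> None:
        if len(self._store) > self.peak_resident_slots:
            self.peak_resident_slots = len(self._store)

    def count_stored_entries(self) -> int:
        """Total stored CLV pattern-columns across nodes and partitions."""
        return sum(sum(clv.shape[1] for clv, _ in parts)
                   for parts in self._store.values())

    def _root_reduce(self, root: int) -> float:
        total = 0.0
        for p, part in enumerate(self.patterns.partitions):
            model = self._models.model(p)
            g = self._models.gamma(p)
            clv, scale = self._store[root][p]
            site = np.tensordot(clv, model.frequencies, axes=(2, 0))  # (k, pat)
            site = g.probs @ site
            if np.any(site <= 0):
                raise LikelihoodError(
                    f"zero site likelihood in partition {part.name!r}")
            logs = np.log(site) - _LOG_RESCALE * scale
            total += float(part.weights @ logs)
        if not np.isfinite(total):
            raise LikelihoodError("non-finite log-likelihood")
        return total

    # ------------------------------------------------------------------- SEV

    def _loglik_sev(self, tree: Tree) -> float:
        root = tree.eval_root()
        order = tree.postorder(root)
        n_parts = len(self.patterns.partitions)
        total = 0.0
        self._store.clear()
        self._sigs.clear()
        entries = 0
        for p, part in enumerate(self.patterns.partitions):
            model = self._models.model(p)
            g = self._models.gamma(p)
            bl = self._models.bl_groups[p]
            n_pat = part.n_patterns
            all_idx = np.arange(n_pat)
            miss: dict[int, np.ndarray] = {}
            active: dict[int, np.ndarray] = {}
            store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for t_ in range(self.n_taxa):
                miss[t_] = part.tip_all_missing(t_)
                active[t_] = np.nonzero(~miss[t_])[0]
            for node, children in order:
                if node < self.n_taxa and node != root:
                    continue
                m = np.ones(n_pat, dtype=bool)
                for c, _ in children:
                    m &= miss[c]
                if node < self.n_taxa:      # two-taxon case: root is a leaf
                    m &= miss[node]
                miss[node] = m
                act = np.nonzero(~m)[0]
                active[node] = act
                k = g.n_categories
                s = part.n_states
                clv = np.ones((k, act.size, s))
                scale = np.zeros(act.size, dtype=np.int32)
                for c, e in children:
                    t = tree.lengths[e][bl]
                    P = model.transition_probs(t, g.rates)
                    PT = np.ascontiguousarray(P.transpose(0, 2, 1))
                    pos = np.searchsorted(act, active[c])
                    if c < self.n_taxa:
                        sub = self._tip(c, p)[active[c]]
                        contrib = np.matmul(sub[None, :, :], PT)
                    else:
                        child_clv, child_scale = store[c]
                        contrib = np.matmul(child_clv, PT)
                        scale[pos] += child_scale
                    clv[:, pos, :] *= contrib
                if node < self.n_taxa:
                    clv *= self._tip(node, p)[active[node]][None, :, :]
                if act.size:
                    pmax = clv.max(axis=(0, 2))
                    small = (pmax < _RESCALE_THRESH) & (pmax > 0)
                    if small.any():
                        clv[:, small, :] *= _RESCALE_FACTOR
                        scale = scale + small.astype(np.int32)
                store[node] = (clv, scale)
                entries += act.size
                # free children no longer needed
                for c, _ in children:
                    store.pop(c, None)
            clv, scale = store[root]
            act = active[root]
            site_active = g.probs @ np.tensordot(clv, model.frequencies, axes=(2, 0))
            site = np.ones(n_pat)
            site[act] = site_active
            logs = np.log(site)
            logs[act] -= _LOG_RESCALE * scale
            total += float(part.weights @ logs)
        self.clv_entries_stored = entries
        if not np.isfinite(total):
            raise LikelihoodError("non-finite log-likelihood")
        return total


# ------------------------------------------------------- functional surface

def compute_loglik(tree: Tree, models, gammas, pattern_matrix: PatternMatrix,
                   bl_groups: Sequence[int] | None = None,
                   mem_mode: str = "full") -> float:
    """One-shot pruning log-likelihood (builds a throwaway engine)."""
    eng = LikelihoodEngine(pattern_matrix, models=models, gammas=gammas,
                           bl_groups=bl_groups, mem_mode=mem_mode)
    return eng.loglik(tree)


def compute_loglik_sev(tree: Tree, models, gammas,
                       pattern_matrix: PatternMatrix,
                       bl_groups: Sequence[int] | None = None) -> float:
    """Pruning log-likelihood via the missing-data (SEV) evaluation path."""
    eng = LikelihoodEngine(pattern_matrix, models=models, gammas=gammas,
                           bl_groups=bl_groups, use_sev=True)
    return eng.loglik(tree)
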