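"""Unrooted phylogenetic trees with branch lengths.

Trees are stored as undirected adjacency over integer node ids: leaves are
``0 .. n_taxa-1`` (indexing ``taxon_names``), internal nodes are allocated
from ``n_taxa`` upward.  An unrooted binary tree over ``n`` taxa has
``n - 2`` internal nodes (degree 3) and ``2n - 3`` branches.

Branch lengths are expected substitutions per site.  Each branch carries a
vector of lengths, one entry per branch-length linkage group; with fully
linked branch lengths (the default) the vector has a single entry.

Serialization roots the tree at the internal node adjacent to the first
taxon and orders children by the smallest taxon index in their subtree, so
Newick output is deterministic.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np

__all__ = ["Tree", "parse_newick", "write_newick"]


class TreeError(ValueError):
    pass


class Tree:
    """Unrooted tree over a fixed, ordered taxon set."""

    def __init__(self, taxon_names: Sequence[str], n_bl_groups: int = 1):
        names = list(taxon_names)
        if len(set(names)) != len(names):
            raise TreeError("duplicate taxon names")
        self.taxon_names = names
        self.n_taxa = len(names)
        self.n_bl_groups = n_bl_groups
        # adjacency[a][b] = edge id; edges[eid] = (a, b); lengths[eid] = array(G)
        self.adjacency: dict[int, dict[int, int]] = {i: {} for i in range(self.n_taxa)}
        self.edges: dict[int, tuple[int, int]] = {}
        self.lengths: dict[int, np.ndarray] = {}
        self._next_node = self.n_taxa
        self._next_edge = 0

    # ------------------------------------------------------------------ basics

    def new_node(self) -> int:
        node = self._next_node
        self._next_node += 1
        self.adjacency[node] = {}
        return node

    def add_edge(self, a: int, b: int, length: float | np.ndarray = 0.1) -> int:
        eid = self._next_edge
        self._next_edge += 1
        self.adjacency[a][b] = eid
        self.adjacency[b][a] = eid
        self.edges[eid] = (a, b)
        vec = np.asarray(length, dtype=float)
        if vec.ndim == 0:
            vec = np.full(self.n_bl_groups, float(vec))
        self.lengths[eid] = vec.copy()
        return eid

    def remove_edge(self, eid: int) -> None:
        a, b = self.edges.pop(eid)
        del self.adjacency[a][b]
        del self.adjacency[b][a]
        del self.lengths[eid]

    def remove_node(self, node: int) -> None:
        if self.adjacency[node]:
            raise TreeError(f"node {node} still has incident edges")
        del self.adjacency[node]

    def neighbors(self, node: int) -> list[int]:
        return list(self.adjacency[node])

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    def edge_between(self, a: int, b: int) -> int:
        return self.adjacency[a][b]

    def branch_length(self, eid: int, group: int = 0) -> float:
        return float(self.lengths[eid][group])

    def set_branch_length(self, eid: int, value: float, group: int = 0) -> None:
        if value <= 0:
            raise TreeError("branch lengths must be positive")
        self.lengths[eid][group] = value

    @property
    def nodes(self) -> list[int]:
        return list(self.adjacency)

    @property
    def internal_nodes(self) -> list[int]:
        return [v for v in self.adjacency if v >= self.n_taxa]

    def edge_ids(self) -> list[int]:
        """Branch ids in a deterministic (sorted) order."""
        return sorted(self.edges)

    def internal_edge_ids(self) -> list[int]:
        return [e for e in self.edge_ids()
                if self.edges[e][0] >= self.n_taxa and self.edges[e][1] >= self.n_taxa]

    def tree_length(self, group: int = 0) -> float:
        return float(sum(self.lengths[e][group] for e in self.edges))

    def copy(self) -> "Tree":
        t = Tree(self.taxon_names, self.n_bl_groups)
        t.adjacency = {v: dict(nb) for v, nb in self.adjacency.items()}
        t.edges = dict(self.edges)
        t.lengths = {e: v.copy() for e, v in self.lengths.items()}
        t._next_node = self._next_node
        t._next_edge = self._next_edge
        return t

    def validate(self) -> None:
        n = self.n_taxa
        if len(self.edges) != 2 * n - 3 and n >= 3:
            raise TreeError(f"expected {2 * n - 3} branches, found {len(self.edges)}")
        for v in self.adjacency:
            deg = self.degree(v)
            if v < n and deg != 1:
                raise TreeError(f"leaf {v} has degree {deg}")
            if v >= n and deg != 3:
                raise TreeError(f"internal node {v} has degree {deg}")
        seen = set()
        stack = [next(iter(self.adjacency))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(u for u in self.adjacency[v] if u not in seen)
        if len(seen) != len(self.adjacency):
            raise TreeError("tree is not connected")
        for e, vec in self.lengths.items():
            if np.any(vec <= 0):
                raise TreeError(f"non-positive length on branch {e}")

    # -------------------------------------------------------------- traversal

    def postorder(self, root: int) -> list[tuple[int, list[tuple[int, int]]]]:
        """Post-order list of ``(node, [(child, edge_id), ...])`` rooted at *root*.

        The root entry lists all its neighbors as children; every other node
        lists its neighbors away from the root.  Children are ordered by node
        id for determinism.
        """
        order: list[tuple[int, list[tuple[int, int]]]] = []
        stack: list[tuple[int, int | None, bool]] = [(root, None, False)]
        while stack:
            node, parent, expanded = stack.pop()
            children = sorted(u for u in self.adjacency[node] if u != parent)
            if expanded:
                order.append((node, [(c, self.adjacency[node][c]) for c in children]))
            else:
                stack.append((node, parent, True))
                for c in children:
                    stack.append((c, node, False))
        return order

    def eval_root(self) -> int:
        """The internal node adjacent to taxon 0 (canonical evaluation root)."""
        if self.n_taxa == 2:
            return 1
        return next(iter(self.adjacency[0]))

    def leaves_below(self, node: int, parent: int) -> list[int]:
        out = []
        stack = [(node, parent)]
        while stack:
            v, p = stack.pop()
            if v < self.n_taxa:
                out.append(v)
            stack.extend((u, v) for u in self.adjacency[v] if u != p)
        return out

    # ------------------------------------------------------------------ splits

    def splits(self, include_trivial: bool = False) -> set[int]:
        """Bipartitions as canonical bitmasks over taxon indices.

        Each branch induces a split; the canonical key is the side that does
        not contain taxon 0.  Pendant (trivial) splits are excluded unless
        requested.
        """
        n = self.n_taxa
        full = (1 << n) - 1
        out: set[int] = set()
        for eid, (a, b) in self.edges.items():
            side = self._side_mask(a, b)
            trivial = side & (side - 1) == 0 or (full ^ side) & ((full ^ side) - 1) == 0
            if trivial and not include_trivial:
                continue
            out.add(side)
        return out

    def _side_mask(self, a: int, b: int) -> int:
        """Bitmask of the taxa on ``a``'s side of edge (a, b), canonicalized
        to the side not containing taxon 0."""
        mask = 0
        for leaf in self.leaves_below(a, b):
            mask |= 1 << leaf
        if mask & 1:
            mask = ((1 << self.n_taxa) - 1) ^ mask
        return mask

    def split_of_edge(self, eid: int) -> int:
        a, b = self.edges[eid]
        return self._side_mask(a, b)

    # ------------------------------------------------------------------ newick

    def newick(self, precision: int = 6, group: int = 0,
               support: dict[int, float] | None = None) -> str:
        root = self.eval_root()
        if self.n_taxa == 2:
            e = self.adjacency[0][1]
            bl = self.branch_length(e, group)
            return (f"({self.taxon_names[0]}:{bl:.{precision}f},"
                    f"{self.taxon_names[1]}:{bl:.{precision}f});")

        min_leaf: dict[int, int] = {}
        for node, children in self.postorder(root):
            if node < self.n_taxa:
                min_leaf[node] = node
            else:
                vals = [min_leaf[c] for c, _ in children]
                min_leaf[node] = min(vals) if vals else self.n_taxa

        def render(node: int, parent: int) -> str:
            children = sorted((u for u in self.adjacency[node] if u != parent),
                              key=lambda c: min_leaf.get(c, c))
            eid = self.adjacency[node][parent]
            bl = self.branch_length(eid, group)
            if node < self.n_taxa:
                return f"{self.taxon_names[node]}:{bl:.{precision}f}"
            inner = ",".join(render(c, node) for c in children)
            label = ""
            if support is not None:
                sup = support.get(self.split_of_edge(eid))
                if sup is not None:
                    label = f"{sup:.3f}"
            return f"({inner}){label}:{bl:.{precision}f}"

        top = sorted(self.adjacency[root], key=lambda c: min_leaf.get(c, c))
        return "(" + ",".join(render(c, root) for c in top) + ");"

    # ----------------------------------------------------------- constructors

    @classmethod
    def from_random_joins(cls, taxon_names: Sequence[str], rng: np.random.Generator,
                          branch_length: float = 0.1, n_bl_groups: int = 1) -> "Tree":
        """Random topology by sequential random joining of lineages.

        Repeatedly picks a uniform pair of lineages and joins them under a
        new internal node until three remain, which are joined at the final
        internal node.  At n = 4 this is uniform over the three unrooted
        topologies.
        """
        t = cls(taxon_names, n_bl_groups)
        n = t.n_taxa
        if n < 2:
            raise TreeError("need at least 2 taxa")
        if n == 2:
            t.add_edge(0, 1, branch_length)
            return t
        if n == 3:
            c = t.new_node()
            for leaf in range(3):
                t.add_edge(c, leaf, branch_length)
            return t
        lineages = list(range(n))
        while len(lineages) > 3:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            a, b = lineages[i], lineages[j]
            parent = t.new_node()
            t.add_edge(parent, a, branch_length)
            t.add_edge(parent, b, branch_length)
            lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
            lineages.append(parent)
        hub = t.new_node()
        for a in lineages:
            t.add_edge(hub, a, branch_length)
        t.validate()
        return t


# ---------------------------------------------------------------------- parse

_TOKEN = re.compile(r"\s*([(),;]|:[^,();\s]+|[^,():;\s]+)")


def parse_newick(text: str, taxon_names: Sequence[str] | None = None) -> Tree:
    """Parse a Newick string into an unrooted :class:`Tree`.

    Rooted input (a degree-2 root) is unrooted by merging the root's two
    incident branches (lengths added).  If *taxon_names* is given, leaf
    labels must be drawn from it and index into it; otherwise taxa are
    indexed in order of first appearance.
    """
    text = re.sub(r"\[[^\]]*\]", "", text)      # strip comments ([&R], figtree)
    tokens = _TOKEN.findall(text)
    if not tokens or tokens[-1] != ";":
        raise TreeError("Newick string must end with ';'")
    pos = 0

    # node spec: (children, name, length)
    def parse_clade():
        nonlocal pos
        children = []
        name = None
        length = None
        if tokens[pos] == "(":
            pos += 1
            while True:
                children.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise TreeError("unbalanced parentheses in Newick string")
        if pos < len(tokens) and tokens[pos] not in "(),;" and not tokens[pos].startswith(":"):
            name = tokens[pos]
            pos += 1
        if pos < len(tokens) and tokens[pos].startswith(":"):
            try:
                length = float(tokens[pos][1:])
            except ValueError as exc:
                raise TreeError(f"bad branch length {tokens[pos][1:]!r}") from exc
            pos += 1
        return (children, name, length)

    root_spec = parse_clade()
    if pos >= len(tokens) or tokens[pos] != ";":
        raise TreeError("unbalanced parentheses in Newick string")

    # collect leaf names in appearance order
    leaves: list[str] = []

    def collect(spec):
        children, name, _ = spec
        if not children:
            if not name:
                raise TreeError("leaf without a name")
            leaves.append(name)
        for c in children:
            collect(c)

    collect(root_spec)
    if taxon_names is None:
        names = leaves
    else:
        names = list(taxon_names)
        unknown = set(leaves) - set(names)
        if unknown:
            raise TreeError(f"unknown taxa in Newick string: {sorted(unknown)}")
        if set(leaves) != set(names):
            raise TreeError("Newick string does not cover the expected taxon set")
    if len(set(leaves)) != len(leaves):
        raise TreeError("duplicate leaf names in Newick string")
    index = {nm: i for i, nm in enumerate(names)}

    t = Tree(names)
    default_len = 0.1

    def build(spec) -> tuple[int, float]:
        children, name, length = spec
        bl = default_len if length is None else length
        if not children:
            return index[name], bl
        node = t.new_node()
        for c in children:
            child, child_bl = build(c)
            t.add_edge(node, child, child_bl)
        return node, bl

    children, _, _ = root_spec
    if len(children) == 1:
        root_spec = (children[0][0], children[0][1], None)
        children = root_spec[0]
    root = t.new_node()
    for c in children:
        child, bl = build(c)
        t.add_edge(root, child, bl)

    # unroot: merge through any degree-2 node (rooted input)
    for node in list(t.adjacency):
        if node >= t.n_taxa and t.degree(node) == 2:
            (a, ea), (b, eb) = [(u, t.adjacency[node][u]) for u in t.neighbors(node)]
            merged = t.lengths[ea] + t.lengths[eb]
            t.remove_edge(ea)
            t.remove_edge(eb)
            t.remove_node(node)
            t.add_edge(a, b, merged)
    if t.n_taxa >= 3:
        t.validate()
    return t


def write_newick(tree: Tree, precision: int = 6, group: int = 0) -> str:
    return tree.newick(precision=precision, group=group)
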