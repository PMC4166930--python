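"""Post-run summaries: consensus trees, convergence diagnostics, sample
statistics, Robinson–Foulds distances and tree-space embedding.

Topological summaries work on *splits* (bipartitions of the taxon set
induced by branches), stored as canonical bitmasks — the side not
containing the first taxon.  The convergence diagnostic is the average
standard deviation of split frequencies (ASDSF) across independent runs;
values below about 0.01 are conventionally read as topological
convergence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tree import Tree, parse_newick

__all__ = [
    "SplitTable", "split_frequencies", "consensus_tree", "asdsf",
    "sample_stats", "rf_distance", "mds_embed", "splits_compatible",
    "read_topologies_nexus",
]


@dataclass
class SplitTable:
    """Split → (count, frequency, mean branch length) for one tree sample."""

    taxon_names: list[str]
    n_samples: int = 0
    counts: dict[int, int] = field(default_factory=dict)
    length_sums: dict[int, float] = field(default_factory=dict)
    # lengths are tracked for trivial (pendant) splits too, so they carry
    # their own occurrence counter
    length_counts: dict[int, int] = field(default_factory=dict)

    def frequency(self, split: int) -> float:
        return self.counts.get(split, 0) / self.n_samples if self.n_samples else 0.0

    def frequencies(self) -> dict[int, float]:
        return {s: c / self.n_samples for s, c in self.counts.items()}

    def mean_length(self, split: int) -> float | None:
        c = self.length_counts.get(split)
        return self.length_sums[split] / c if c else None


def _as_trees(tree_samples: Iterable[Tree | str],
              taxon_names: Sequence[str] | None) -> list[Tree]:
    trees = []
    for t in tree_samples:
        if isinstance(t, str):
            t = parse_newick(t, taxon_names)
        elif taxon_names is not None and list(t.taxon_names) != list(taxon_names):
            raise ValueError("taxon set mismatch among tree samples")
        trees.append(t)
    return trees


def split_frequencies(tree_samples: Iterable[Tree | str],
                      burnin_fraction: float = 0.0,
                      taxon_names: Sequence[str] | None = None) -> SplitTable:
    """Tabulate split frequencies over post-burn-in samples.

    Pendant (trivial) splits are excluded from frequencies but their branch
    lengths are still accumulated for consensus annotation.
    """
    samples = list(tree_samples)
    start = int(len(samples) * burnin_fraction)
    samples = samples[start:]
    if not samples:
        raise ValueError("no post-burn-in samples")
    first = samples[0]
    if taxon_names is None:
        taxon_names = (first.taxon_names if isinstance(first, Tree)
                       else parse_newick(first).taxon_names)
    trees = _as_trees(samples, taxon_names)
    names = set(taxon_names)
    table = SplitTable(list(taxon_names))
    for tree in trees:
        if set(tree.taxon_names) != names:
            raise ValueError("taxon set mismatch among tree samples")
        table.n_samples += 1
        for eid in tree.edges:
            split = tree.split_of_edge(eid)
            length = tree.branch_length(eid)
            n_bits = bin(split).count("1")
            trivial = n_bits <= 1 or n_bits >= tree.n_taxa - 1
            table.length_sums[split] = table.length_sums.get(split, 0.0) + length
            table.length_counts[split] = table.length_counts.get(split, 0) + 1
            if trivial:
                continue
            table.counts[split] = table.counts.get(split, 0) + 1
    return table


def splits_compatible(a: int, b: int, n_taxa: int) -> bool:
    """Two splits are compatible iff some pair of their sides is disjoint."""
    full = (1 << n_taxa) - 1
    return (a & b == 0 or (a & ~b & full) == 0 or (~a & b & full) == 0
            or ((full ^ a) & (full ^ b)) == 0)


def consensus_tree(table: SplitTable, threshold: float = 0.5,
                   extended: bool = False) -> tuple[Tree, dict[int, float]]:
    """Majority-rule consensus (optionally extended/greedy).

    Includes every nontrivial split with frequency > *threshold*; in
    extended mode remaining splits are added in order of descending
    frequency (ties by bitmask) when compatible with the tree so far.
    Returns the (possibly multifurcating) consensus tree and a
    split → support map; branch lengths are mean lengths over the samples
    containing the branch.
    """
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 does not guarantee compatibility")
    names = table.taxon_names
    n = len(names)
    freqs = table.frequencies()
    chosen = [s for s, f in freqs.items() if f > threshold]
    if extended:
        rest = sorted((s for s, f in freqs.items() if f <= threshold),
                      key=lambda s: (-freqs[s], s))
        for s in rest:
            if all(splits_compatible(s, c, n) for c in chosen):
                chosen.append(s)
    chosen.sort(key=lambda s: bin(s).count("1"))

    tree = Tree(names)
    hub = tree.new_node()
    parent = {leaf: hub for leaf in range(n)}
    children: dict[int, set[int]] = {hub: set(range(n))}
    leafset: dict[int, int] = {leaf: 1 << leaf for leaf in range(n)}
    leafset[hub] = (1 << n) - 1

    for s in chosen:
        members = [i for i in range(n) if s >> i & 1]
        # climb to the highest ancestor still contained in the split
        node = members[0]
        while node != hub and leafset[parent[node]] & ~s == 0:
            node = parent[node]
        v = parent[node]
        sub = {c for c in children[v] if leafset[c] & ~s == 0}
        if sum(bin(leafset[c]).count("1") for c in sub) != len(members):
            continue        # incompatible with an earlier split (extended ties)
        u = tree.new_node()
        for c in sub:
            children[v].discard(c)
            parent[c] = u
        children[u] = sub
        children[v].add(u)
        parent[u] = v
        leafset[u] = s

    def mean_len(split: int, fallback: float = 0.1) -> float:
        m = table.mean_length(split)
        if m is None:
            full = (1 << n) - 1
            m = table.mean_length(full ^ split)
        return m if m is not None else fallback

    for node, kids in children.items():
        for c in kids:
            tree.add_edge(node, c, mean_len(leafset[c]))
    support = {s: freqs[s] for s in chosen}
    return tree, support


def asdsf(runs_split_tables: Sequence[SplitTable], min_freq: float = 0.1) -> float:
    """Average (across splits) standard deviation (across runs) of split
    frequencies, over splits reaching *min_freq* in at least one run.

    Population SD (divide by the number of runs).  The conventional
    convergence rule of thumb is ASDSF < 0.01.
    """
    if len(runs_split_tables) < 2:
        raise ValueError("ASDSF needs at least two runs")
    if not (0 <= min_freq < 1):
        raise ValueError("min_freq must be in [0, 1)")
    all_splits = set()
    per_run = [t.frequencies() for t in runs_split_tables]
    for f in per_run:
        all_splits.update(s for s, v in f.items() if v >= min_freq)
    if not all_splits:
        return 0.0
    sds = []
    for s in sorted(all_splits):
        vals = np.array([f.get(s, 0.0) for f in per_run])
        sds.append(vals.std())        # population convention
    return float(np.mean(sds))


def effective_sample_size(x: np.ndarray) -> tuple[float, bool]:
    """ESS = n / (1 + 2 Σ ρ_k), autocorrelations summed until the first
    non-positive value.  Returns (ess, degenerate) where degenerate flags a
    constant trace (reported as ESS = n)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    var = x.var()
    if var == 0 or n < 4:
        return float(n), True
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (var * n)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s)), False


def sample_stats(trace: pd.DataFrame, burnin_fraction: float = 0.0) -> pd.DataFrame:
    """Per-parameter posterior summaries: mean, median, central 95%
    credible interval (equal-tailed) and ESS."""
    start = int(len(trace) * burnin_fraction)
    post = trace.iloc[start:]
    rows = []
    for col in post.columns:
        x = post[col].to_numpy(dtype=float)
        ess, degenerate = effective_sample_size(x)
        rows.append({
            "parameter": col,
            "mean": x.mean(),
            "median": float(np.median(x)),
            "ci_lower": float(np.quantile(x, 0.025)),
            "ci_upper": float(np.quantile(x, 0.975)),
            "ess": ess,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index("parameter")


def _name_splits(tree: Tree, ref: str) -> set[frozenset]:
    out = set()
    for s in tree.splits():
        side = frozenset(tree.taxon_names[i] for i in range(tree.n_taxa)
                         if s >> i & 1)
        if ref in side:
            side = frozenset(tree.taxon_names) - side
        out.add(side)
    return out


def rf_distance(tree_a: Tree, tree_b: Tree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    two trees' nontrivial split sets."""
    if set(tree_a.taxon_names) != set(tree_b.taxon_names):
        raise ValueError("trees are over different taxon sets")
    ref = sorted(tree_a.taxon_names)[0]
    sa = _name_splits(tree_a, ref)
    sb = _name_splits(tree_b, ref)
    return len(sa ^ sb)


def mds_embed(distance_matrix: np.ndarray, dim: int = 2,
              jitter_seed: int = 0) -> np.ndarray:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centering followed by the top-``dim`` spectral coordinates.  An
    exactly ``dim``-dimensional Euclidean input is reproduced up to rigid
    motion.  Exact duplicates (distance 0) then receive a deterministic,
    seeded jitter of radius 1e-3 × max distance so identical trees map to
    adjacent, non-identical positions.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("need a symmetric nonnegative matrix with zero diagonal")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1][:dim]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))

    # deterministic jitter for exact duplicates
    rng = np.random.default_rng(jitter_seed)
    radius = 1e-3 * (D.max() if D.max() > 0 else 1.0)
    seen: dict[bytes, int] = {}
    for i in range(m):
        key = D[i].tobytes()
        if key in seen:
            angle_raw = rng.random(dim)
            offset = (angle_raw - 0.5)
            norm = np.linalg.norm(offset) or 1.0
            coords[i] += offset / norm * radius * (0.25 + 0.75 * rng.random())
        else:
            seen[key] = i
    return coords


def read_topologies_nexus(path) -> tuple[list[str], list[str]]:
    """Read a Nexus trees block with a translate table; returns
    (newick strings with names restored, taxon names)."""
    text = open(path).read()
    tr = re.search(r"translate(.*?);", text, re.S | re.I)
    mapping = {}
    if tr:
        for num, name in re.findall(r"(\d+)\s+([^\s,;]+)", tr.group(1)):
            mapping[num] = name
    names = [mapping[k] for k in sorted(mapping, key=int)]
    newicks = []
    for line in re.findall(r"tree\s+\S+\s*=\s*(?:\[[^\]]*\]\s*)?([^;]+;)", text):
        nwk = re.sub(r"(\d+)(?=:)", lambda mch: mapping.get(mch.group(1),
                                                            mch.group(1)), line)
        newicks.append(nwk.strip())
    return newicks, names
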