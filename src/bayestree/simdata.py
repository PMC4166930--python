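"""Synthetic data: bush-like trees, GTR+Γ alignments, block missingness.

The generator emulates the regime that makes genome-scale tree inference
hard: a bush-like topology (long outer branches, short hard-to-resolve
inner branches), partitioned alignments of configurable size, and
block-structured missing data as produced by patchy ortholog sampling,
with missing fractions up to and beyond 75%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolmodel import GammaRates, SubstModel, build_model, discretize_gamma
from .msa_io import AA_STATES, Alignment, DNA_STATES, PartitionDef
from .tree import Tree

__all__ = ["SimConfig", "generate_bushy_tree", "simulate_alignment",
           "apply_missingness", "simulate_dataset"]


@dataclass
class SimConfig:
    """The scaled-down replay profile: 20 taxa, 10 partitions × 1,000 sites
    by default (a 1% scale model of a 200-taxon, 100-partition design)."""

    n_taxa: int = 20
    outer_branch_length: float = 0.3
    inner_branch_length: float = 0.03
    n_partitions: int = 10
    sites_per_partition: int = 1000
    alpha: float = 0.5
    missing_fraction: float = 0.0
    block_missing: bool = True
    jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.outer_branch_length <= 0 or self.inner_branch_length <= 0:
            raise ValueError("branch lengths must be positive")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing fraction must be in [0, 1)")


def generate_bushy_tree(n_taxa: int, outer_len: float = 0.3,
                        inner_len: float = 0.03,
                        seed: int | np.random.Generator = 0,
                        jitter: bool = False) -> Tree:
    """Random topology with long pendant and short internal branches.

    The topology is drawn by sequential random joins (uniform over the
    three unrooted topologies at n = 4); pendant branches get
    ``outer_len`` and internal branches ``inner_len``, each optionally
    jittered ±20% (seeded).
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"t{i}" for i in range(n_taxa)]
    tree = Tree.from_random_joins(names, rng)
    for eid, (a, b) in tree.edges.items():
        pendant = a < n_taxa or b < n_taxa
        length = outer_len if pendant else inner_len
        if jitter:
            length *= 1.0 + 0.2 * (2 * rng.random() - 1)
        tree.lengths[eid][:] = length
    return tree


def _evolve(parent_states: np.ndarray, P: np.ndarray, cats: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states, per-category transition
    matrices P (k, s, s) and per-site category indices."""
    child = np.empty_like(parent_states)
    u = rng.random(parent_states.size)
    for k in range(P.shape[0]):
        sel = cats == k
        if not sel.any():
            continue
        cum = np.cumsum(P[k], axis=1)
        child[sel] = (u[sel, None] > cum[parent_states[sel]]).sum(axis=1)
    return np.minimum(child, P.shape[1] - 1)


def simulate_alignment(tree: Tree, models, gammas, sites_per_partition,
                       seed: int | np.random.Generator = 0,
                       partition_names: list[str] | None = None
                       ) -> tuple[Alignment, list[PartitionDef]]:
    """Simulate sequences along *tree* partition by partition.

    Root states are drawn from the stationary frequencies; each site draws
    a uniform Γ category and evolves along every branch with
    ``P(t · rate)``.  Returns the alignment and matching partition
    definitions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(models, SubstModel):
        models = [models]
    if isinstance(gammas, GammaRates):
        gammas = [gammas] * len(models)
    if np.isscalar(sites_per_partition):
        sites_per_partition = [int(sites_per_partition)] * len(models)
    n = tree.n_taxa
    root = tree.eval_root()
    order = tree.postorder(root)
    columns = []
    partition_defs = []
    offset = 0
    for p, (model, gamma, n_sites) in enumerate(zip(models, gammas,
                                                    sites_per_partition)):
        s = model.n_states
        states_alpha = DNA_STATES if s == 4 else AA_STATES
        cats = rng.integers(gamma.n_categories, size=n_sites)
        node_states = {root: rng.choice(s, size=n_sites, p=model.frequencies)}
        # pre-order walk from the evaluation root
        for node, children in reversed(order):
            for c, eid in children:
                t = tree.branch_length(eid)
                P = model.transition_probs(t, gamma.rates)
                node_states[c] = _evolve(node_states[node], P, cats, rng)
        mat = np.empty((n, n_sites), dtype="<U1")
        lut = np.array(list(states_alpha))
        for taxon in range(n):
            mat[taxon] = lut[node_states[taxon]]
        columns.append(mat)
        name = (partition_names[p] if partition_names else f"p{p}")
        partition_defs.append(PartitionDef(
            name, "DNA" if s == 4 else "AA",
            [(offset + 1, offset + n_sites, 1)]))
        offset += n_sites
    full = np.concatenate(columns, axis=1)
    data_type = "DNA" if models[0].n_states == 4 else "AA"
    return Alignment(list(tree.taxon_names), full, data_type), partition_defs


def apply_missingness(alignment: Alignment, fraction: float,
                      block_structured: bool = True,
                      seed: int | np.random.Generator = 0,
                      partitions: list[PartitionDef] | None = None,
                      n_blocks: int = 10) -> Alignment:
    """Replace characters with '?' until *fraction* of the matrix is
    missing (realized fraction within 1% of the target).

    Block mode removes whole (taxon × partition) blocks, emulating absent
    orthologs; site mode removes uniformly random cells.  Every taxon
    keeps at least one observed character.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return alignment
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = alignment.matrix.copy()
    n_taxa, n_sites = mat.shape
    target = fraction * n_taxa * n_sites
    if block_structured:
        if partitions is not None:
            col_blocks = [p.columns() for p in partitions]
        else:
            col_blocks = [np.asarray(b) for b in
                          np.array_split(np.arange(n_sites), n_blocks)]
        cells = [(t, b) for t in range(n_taxa) for b in range(len(col_blocks))]
        perm = rng.permutation(len(cells))
        removed = 0
        blocks_left = {t: len(col_blocks) for t in range(n_taxa)}
        for idx in perm:
            if removed >= target:
                break
            t, b = cells[idx]
            if blocks_left[t] <= 1:
                continue        # keep every taxon represented
            cols = col_blocks[b]
            mat[t, cols] = "?"
            blocks_left[t] -= 1
            removed += cols.size
        if removed < target * 0.99 - n_sites / n_blocks:
            raise ValueError("missing fraction too high while keeping every "
                             "taxon represented")
    else:
        n_cells = n_taxa * n_sites
        k = int(round(fraction * n_cells))
        idx = rng.choice(n_cells, size=k, replace=False)
        rows, cols = np.unravel_index(idx, mat.shape)
        mat[rows, cols] = "?"
        for t in range(n_taxa):
            if np.all(mat[t] == "?"):
                mat[t, int(rng.integers(n_sites))] = alignment.matrix[
                    t, int(rng.integers(n_sites))]
    return Alignment(alignment.taxon_names, mat, alignment.data_type)


def simulate_dataset(config: SimConfig) -> tuple[Tree, Alignment,
                                                 list[PartitionDef]]:
    """Full replay pipeline: bushy tree → GTR+Γ alignment → missingness."""
    rng = np.random.default_rng(config.seed)
    tree = generate_bushy_tree(config.n_taxa, config.outer_branch_length,
                               config.inner_branch_length, rng,
                               jitter=config.jitter)
    models = []
    gammas = []
    for _ in range(config.n_partitions):
        ex = rng.dirichlet(np.full(6, 10.0))
        fr = rng.dirichlet(np.full(4, 50.0))
        models.append(build_model("DNA", ex, fr))
        gammas.append(discretize_gamma(config.alpha))
    aln, parts = simulate_alignment(tree, models, gammas,
                                    config.sites_per_partition, rng)
    if config.missing_fraction > 0:
        aln = apply_missingness(aln, config.missing_fraction,
                                config.block_missing, rng, partitions=parts)
    return tree, aln, parts
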