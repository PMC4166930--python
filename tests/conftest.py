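"""Shared fixtures: small random alignments, trees and models."""

import numpy as np
import pytest

from bayestree.evolmodel import build_model, discretize_gamma
from bayestree.msa_io import Alignment, compress_patterns
from bayestree.tree import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_alignment(n_taxa, n_sites, rng, alphabet="ACGT"):
    names = [f"t{i}" for i in range(n_taxa)]
    mat = rng.choice(list(alphabet), size=(n_taxa, n_sites))
    return Alignment(names, mat)


def random_instance(rng, n_taxa=5, n_sites=20):
    """A random (tree, model, gamma, patterns) quadruple."""
    names = [f"t{i}" for i in range(n_taxa)]
    tree = Tree.from_random_joins(names, rng, 0.2)
    for e in tree.edge_ids():
        tree.set_branch_length(e, float(rng.uniform(0.02, 0.6)))
    aln = random_alignment(n_taxa, n_sites, rng)
    model = build_model("DNA", rng.dirichlet(np.ones(6) * 5),
                        rng.dirichlet(np.ones(4) * 5))
    gamma = discretize_gamma(float(rng.uniform(0.3, 2.0)), 4)
    return tree, model, gamma, compress_patterns(aln), aln


@pytest.fixture
def five_taxon_instance(rng):
    return random_instance(rng)
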