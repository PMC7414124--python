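"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phyloconcord import (
    TaxonMap,
    node_leaf_sets,
    parse_newick,
    simulate_species_tree_with_clades,
)
from phyloconcord.simulate import _yule_join


def random_rooted_tree(rng: np.random.Generator, n_leaves: int,
                       with_lengths: bool = True):
    """A random rooted binary tree over leaves L1..Ln (sequential joins)."""
    labels = [f"L{i + 1}" for i in range(n_leaves)]
    newick = _yule_join(labels, rng, 0.1) + ";"
    tree = parse_newick(newick)
    if not with_lengths:
        for e in tree.preorder_edge_iter():
            e.length = None
    return tree


def all_clades(tree) -> list:
    """Every rooted clade (node leaf set) of the tree, the test oracle's view."""
    return list(node_leaf_sets(tree).values())


def brute_components(tree, taxa) -> set:
    """Independent component oracle: for each taxon, the largest clade that
    contains it and stays inside ``taxa`` (clades containing a fixed leaf
    are nested, so the largest is the maximal one)."""
    taxa = frozenset(taxa)
    clades = all_clades(tree)
    comps = set()
    for t in taxa:
        best = frozenset((t,))
        for c in clades:
            if t in c and c <= taxa and len(c) > len(best):
                best = c
        comps.add(best)
    return comps


@pytest.fixture(scope="session")
def small_species():
    """Desk-scale species tree + taxon map shared by scoring tests."""
    return simulate_species_tree_with_clades(32, 8, seed=20)


@pytest.fixture()
def quartet_map():
    return TaxonMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
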