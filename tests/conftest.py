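"""Shared fixtures and independent oracles for the test suite."""

import itertools

import pytest

from fishtol import load_reference_classification
from fishtol.synthetic_data import simulate_backbone


@pytest.fixture(scope="session")
def reference_taxonomy():
    """The in-package ranked classification of bony fishes."""
    return load_reference_classification()


@pytest.fixture
def cherry():
    from fishtol.tree_io import parse_newick

    return parse_newick("(A:1.0,B:1.0):0.0;")


@pytest.fixture
def quartet():
    from fishtol.tree_io import parse_newick

    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def all_clade_leafsets(tree):
    """Every clade's leaf-label set, computed by explicit recursion.

    Deliberately independent of Phylogeny.leafset (no caching, different
    traversal) so it can serve as an oracle.
    """
    out = []

    def rec(nd):
        if nd.is_leaf():
            leaves = frozenset([nd.label])
        else:
            leaves = frozenset()
            for ch in nd.child_nodes():
                leaves |= rec(ch)
        out.append(leaves)
        return leaves

    rec(tree.root)
    return out


def brute_force_monophyly(tree, tips):
    """Oracle: smallest clade containing the tips, by exhaustive enumeration."""
    tips = frozenset(tips)
    if not tips:
        return "unsampled", []
    if len(tips) == 1:
        return "monotypic", []
    containing = [c for c in all_clade_leafsets(tree) if tips <= c]
    smallest = min(containing, key=len)
    intruders = sorted(smallest - tips)
    return ("monophyletic" if not intruders else "non_monophyletic"), intruders


def random_tree(n_tips, seed):
    """A seeded ultrametric tree for property tests."""
    return simulate_backbone(n_tips, seed=seed)


def leaf_subsets(labels, max_size=None):
    labels = sorted(labels)
    top = len(labels) if max_size is None else max_size
    for k in range(len(labels) + 1):
        if k > top:
            break
        yield from (frozenset(c) for c in itertools.combinations(labels, k))
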