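"""Shared fixtures and hypothesis strategies for random definition trees."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import strategies as st

from named.accessions import Accession
from named.grammar import GAP_STEP, DefinitionNode, enumerate_paths


def leaf_strategy(pool_size: int = 30):
    return st.integers(0, pool_size - 1).map(
        lambda i: DefinitionNode("LEAF", accession=Accession("KO", f"K{i:05d}"))
    )


def _or_node(children):
    return DefinitionNode("OR", tuple(children))


def _and_node(children):
    return DefinitionNode("AND", tuple(children))


def _complex_node(children):
    return DefinitionNode("COMPLEX", tuple(children))


def tree_strategy(
    max_leaves: int = 12,
    allow_gap: bool = True,
    allow_optional: bool = True,
    pool_size: int = 30,
):
    """Random normalised definition trees.

    Children of AND are never AND, children of OR never OR, so the tree is
    already in the parser's normal form and round-trips exactly.
    """
    leaf = leaf_strategy(pool_size)
    atoms = [leaf]
    if allow_gap:
        atoms.append(st.just(DefinitionNode("GAP")))

    def extend(inner):
        complex_child = leaf
        if allow_optional:
            complex_child = st.one_of(
                leaf, leaf.map(lambda n: DefinitionNode("OPTIONAL", (n,)))
            )
        cx = st.tuples(leaf, st.lists(complex_child, min_size=1, max_size=2)).map(
            lambda t: _complex_node((t[0], *t[1]))
        )
        non_or = inner.filter(lambda n: n.kind != "OR")
        or_node = st.lists(non_or, min_size=2, max_size=3).map(_or_node)
        non_and = inner.filter(lambda n: n.kind != "AND")
        and_node = st.lists(non_and, min_size=2, max_size=3).map(_and_node)
        options = [cx, or_node, and_node]
        if allow_optional:
            options.append(
                st.one_of(leaf, cx).map(lambda n: DefinitionNode("OPTIONAL", (n,)))
            )
        return st.one_of(*options)

    return st.recursive(st.one_of(*atoms), extend, max_leaves=max_leaves)


def oracle_completeness(root: DefinitionNode, present: set[Accession]) -> Fraction:
    """Brute-force oracle: exhaustive path enumeration with naive counting."""
    paths, truncated = enumerate_paths(root, max_paths=500_000)
    assert not truncated
    best = Fraction(0)
    for path in paths:
        if not path:
            continue
        sat = sum(1 for step in path if step != GAP_STEP and step <= present)
        best = max(best, Fraction(sat, len(path)))
    return best


@pytest.fixture(scope="session")
def example_modules_path():
    from importlib.resources import files

    return str(files("named").joinpath("data/example_modules.txt"))


@pytest.fixture(scope="session")
def default_suites():
    from importlib.resources import files

    from named.suites import load_suites

    return load_suites(files("named").joinpath("data/suites.tsv"))
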