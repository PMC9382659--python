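"""Shared fixtures: the bundled worked examples plus random-object helpers."""

from __future__ import annotations

import functools
import random

import pytest

from relmat import (
    ArcDiagram,
    GeneratorConfig,
    Relation,
    RelationMatrix,
    fixtures,
    generate_diagram,
)

#: Arc set of the 28-nt pseudoknotted worked example.
PK28_ARCS = frozenset(
    {(1, 7), (2, 6), (8, 11), (12, 24), (13, 23), (14, 17), (18, 27), (19, 22)}
)
PK28_SEQUENCE = "GAUGUGUCAUCAGACCUGCACGCUAGUU"

#: Arc set of the 19-nt concatenated duplex (strand break after vertex 9).
DUPLEX19_ARCS = frozenset(
    {(2, 8), (3, 7), (4, 15), (5, 14), (10, 18), (11, 17), (12, 16)}
)

#: The nine-loop example in enumeration (ascending close) order.
NINE_LOOPS = [(2, 6), (4, 11), (8, 13), (10, 18), (16, 19), (15, 20),
              (9, 24), (22, 27), (21, 28)]


@pytest.fixture(scope="session")
def pk28() -> ArcDiagram:
    return fixtures.pseudoknotted_example()


@pytest.fixture(scope="session")
def duplex19() -> ArcDiagram:
    return fixtures.interaction_example()


@pytest.fixture(scope="session")
def nineloops() -> ArcDiagram:
    return fixtures.nine_loop_example()


@pytest.fixture(scope="session")
def demo_structure() -> RelationMatrix:
    return fixtures.demo_structure_matrix()


@pytest.fixture(scope="session")
def demo_pattern() -> RelationMatrix:
    return fixtures.demo_pattern_matrix()


@functools.lru_cache(maxsize=None)
def random_diagram(seed: int, max_length: int = 60) -> ArcDiagram:
    """One random valid diagram with mixed crossing bias, seeded."""
    r = random.Random(seed)
    length = r.randint(6, max_length)
    n_arcs = r.randint(0, max(0, length // 2 - 1))
    bias = r.choice([0.0, 0.25, 0.5, 0.75, 1.0])
    return generate_diagram(
        GeneratorConfig(length=length, n_arcs=n_arcs, crossing_bias=bias, seed=seed)
    )


def random_matrix(rng: random.Random, n: int) -> RelationMatrix:
    """A random symbol assignment (not necessarily realizable as a diagram;
    matching operates on matrices regardless)."""
    entries = {
        (s, t): rng.choice(list(Relation))
        for s in range(1, n + 1)
        for t in range(s + 1, n + 1)
    }
    return RelationMatrix.from_entries(n, entries)
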