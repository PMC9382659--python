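"""Seeded generators of valid arc diagrams and matrix realization.

:func:`generate_diagram` samples random valid diagrams (endpoint-disjoint
arcs, no neighbour pairing) with a tunable crossing bias: bias 0 yields a
pseudoknot-free diagram by construction, bias 1 forces a pseudoknot
whenever one is feasible.  :func:`realize_matrix` inverts the relation
matrix: it searches, by backtracking interval placement on a 4N-position
grid, for a diagram whose loop enumeration reproduces a given matrix — the
route by which a printed matrix becomes a concrete structure.

All randomness flows through one ``random.Random`` instance seeded from the
config; no global state is touched, so identical configs give identical
output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .abstractions import arcs_cross, is_pseudoknotted
from .diagram import Arc, ArcDiagram
from .errors import (
    InfeasibleConfigError,
    RealizationLimitError,
    UnrealizableMatrixError,
)
from .relations import Relation, RelationMatrix

_BASES = "ACGU"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-diagram generator.

    crossing_bias is the probability that a newly placed arc is required to
    cross an existing one (given any exist); 0 forbids crossings outright.
    """

    length: int
    n_arcs: int
    crossing_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossing_bias <= 1.0:
            raise InfeasibleConfigError(
                f"crossing_bias {self.crossing_bias} outside [0, 1]"
            )
        if self.n_arcs < 0 or self.length < 0:
            raise InfeasibleConfigError("negative length or arc count")
        if 2 * self.n_arcs > self.length:
            raise InfeasibleConfigError(
                f"{self.n_arcs} arcs need {2 * self.n_arcs} vertices, have {self.length}"
            )
        if self.n_arcs >= 1 and self.length < 3:
            raise InfeasibleConfigError(
                "a non-contiguous arc needs at least 3 vertices"
            )
        if (self.crossing_bias == 0.0 and self.n_arcs >= 1
                and self.length < 2 * self.n_arcs + 1):
            # every innermost arc of a non-crossing diagram must enclose an
            # unpaired vertex, so a fully paired backbone cannot be
            # pseudoknot-free
            raise InfeasibleConfigError(
                "a pseudoknot-free diagram needs at least one unpaired vertex"
            )


def generate_diagram(config: GeneratorConfig) -> ArcDiagram:
    """Sample one valid arc diagram under the given configuration."""
    for attempt in range(64):
        rng = random.Random(config.seed * 1_000_003 + attempt)
        # late attempts drop the "non-forced arcs stay non-crossing"
        # preference so dense configurations can still be placed
        relax = attempt >= 6 and config.crossing_bias > 0.0
        arcs = _try_generate(rng, config, relax=relax)
        if arcs is None:
            continue
        if (config.crossing_bias == 1.0 and config.n_arcs >= 2
                and not is_pseudoknotted(ArcDiagram("", config.length, frozenset(arcs)))):
            continue  # bias-1 contract: pseudoknotted whenever feasible
        sequence = "".join(rng.choice(_BASES) for _ in range(config.length))
        return ArcDiagram(sequence=sequence, length=config.length,
                          arcs=frozenset(arcs))
    raise InfeasibleConfigError(
        f"no valid diagram found for length={config.length}, "
        f"n_arcs={config.n_arcs}, crossing_bias={config.crossing_bias}"
    )


def _feasible_noncrossing(length: int, k: int) -> bool:
    # every innermost arc must enclose an unpaired vertex, and a nested
    # chain needs only one: k arcs fit non-crossing iff length >= 2k + 1
    return k == 0 or length >= 2 * k + 1


def _noncrossing_arcs(rng: random.Random, length: int, n_arcs: int) -> list[Arc]:
    """Random non-crossing, non-contiguous arc set, built left to right.

    At each step the first open position either stays unpaired or opens an
    arc; the closing position and the interior/exterior split of the
    remaining arcs are drawn uniformly from the feasible choices, so the
    construction never dead-ends.
    """
    arcs: list[Arc] = []

    def build(start: int, span: int, k: int) -> None:
        while k > 0:
            options: list[tuple[int, int]] = []
            if _feasible_noncrossing(span - 1, k):
                options.append((0, 0))  # leave `start` unpaired
            for q_off in range(2, span):
                interior = q_off - 1
                exterior = span - 1 - q_off
                for k_in in range(k):
                    if (_feasible_noncrossing(interior, k_in)
                            and _feasible_noncrossing(exterior, k - 1 - k_in)):
                        options.append((q_off, k_in))
            q_off, k_in = rng.choice(options)
            if q_off == 0:
                start += 1
                span -= 1
                continue
            arcs.append((start, start + q_off))
            build(start + 1, q_off - 1, k_in)
            start, span, k = start + q_off + 1, span - 1 - q_off, k - 1 - k_in

    build(1, length, n_arcs)
    return arcs


def _try_generate(rng: random.Random, config: GeneratorConfig,
                  relax: bool = False) -> list[Arc] | None:
    """One randomized backtracking pass; None on dead end / budget out."""
    n = config.n_arcs
    if config.crossing_bias == 0.0:
        return _noncrossing_arcs(rng, config.length, n)
    # the first arc has nothing to cross yet
    flags = [False] + [rng.random() < config.crossing_bias
                       for _ in range(max(0, n - 1))]
    free = list(range(1, config.length + 1))
    arcs: list[Arc] = []
    budget = [12_000]  # total pair-tests across the whole search

    def place(k: int) -> bool:
        if k == n:
            return True
        pairs = [
            (i, j)
            for a, i in enumerate(free)
            for j in free[a + 1:]
            if j > i + 1
        ]
        rng.shuffle(pairs)
        # with relax, forced-crossing arcs fall back to any placement after
        # crossing candidates are exhausted; non-forced arcs accept anything
        if flags[k]:
            passes = [True, None] if relax else [True]
        else:
            passes = [None] if relax else [False]
        for want in passes:
            for i, j in pairs:
                budget[0] -= 1
                if budget[0] < 0:
                    return False
                if want is not None:
                    crosses = any(arcs_cross((i, j), arc) for arc in arcs)
                    if crosses != want:
                        continue
                arcs.append((i, j))
                free.remove(i)
                free.remove(j)
                if place(k + 1):
                    return True
                arcs.pop()
                free.append(i)
                free.append(j)
                free.sort()
        return False

    return arcs if place(0) else None


def realize_matrix(matrix: RelationMatrix, node_budget: int = 2_000_000) -> ArcDiagram:
    """Construct a diagram whose relation matrix equals ``matrix``.

    Only the relative order of the 2N endpoints matters, so the search runs
    over endpoint sequences, not grid positions.  Loops are placed in
    enumeration order; because closing positions ascend with the loop index,
    each closing token appends at the end of the sequence, while the opening
    token must fall into the slot interval carved out by the relations to
    the already-placed loops (after C_s for concatenation, before O_s for
    nesting, between O_s and C_s for crossing).  Depth-first search over the
    slots in that interval, smallest slot first, makes the result
    deterministic; an unrealizable matrix exhausts the (finite) search and
    fails loudly.  Finally tokens are laid out left to right one vertex
    apart, with an extra gap inside each arc whose endpoints ended up
    adjacent, so the result is Bpseq-valid (j > i + 1).
    """
    n = matrix.n
    if n == 0:
        return ArcDiagram(sequence="", length=0, arcs=frozenset())
    codes = matrix._codes
    concat, nest = 1, 2  # code values from relations._CODE
    seq: list[tuple[int, int]] = []  # (0, s) = opening of loop s; (1, s) = closing
    nodes = 0

    def place(t: int) -> bool:
        nonlocal nodes
        lo, hi = 0, len(seq)
        for s in range(t):
            code = codes[s, t]
            io = seq.index((0, s))
            if code == concat:
                lo = max(lo, seq.index((1, s)) + 1)
            elif code == nest:
                hi = min(hi, io)
            else:  # cross
                lo = max(lo, io + 1)
                hi = min(hi, seq.index((1, s)))
        for slot in range(lo, hi + 1):
            nodes += 1
            if nodes > node_budget:
                raise RealizationLimitError(
                    f"realization search exceeded {node_budget} nodes at N={n}"
                )
            seq.insert(slot, (0, t))
            seq.append((1, t))
            if t == n - 1 or place(t + 1):
                return True
            seq.pop()
            del seq[slot]
        return False

    if not place(0):
        raise UnrealizableMatrixError(
            f"no endpoint ordering satisfies the {n}-loop matrix"
        )

    positions: list[int] = []
    for k, token in enumerate(seq):
        if not positions:
            positions.append(1)
            continue
        step = 1
        kind, s = token
        if kind == 1 and seq[k - 1] == (0, s):
            step = 2  # keep the pair non-contiguous
        positions.append(positions[-1] + step)
    where = dict(zip(seq, positions))
    arcs = frozenset((where[(0, s)], where[(1, s)]) for s in range(n))
    length = positions[-1]
    return ArcDiagram(sequence="N" * length, length=length, arcs=arcs)
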