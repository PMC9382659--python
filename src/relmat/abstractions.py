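"""Core and shadow abstractions of arc diagrams.

The *core* of a diagram deletes every unpaired vertex and collapses each
maximal run of parallel arcs (a helix/stack) to a single arc, then renumbers
the surviving endpoints 1, 2, ...  The *shadow* first keeps only arcs that
cross at least one other arc — the pseudoknot skeleton — then collapses and
renumbers the same way.  A diagram is pseudoknotted exactly when its shadow
is nonempty.

Two arcs (i1, j1), (i2, j2) are *parallel* (stacked) iff i1 = i2 - 1 and
j2 = j1 + 1, i.e. immediately adjacent on both sides.  Parallelism and
crossing are always evaluated on the ORIGINAL coordinates, before any
deletion or renumbering; arcs that become coordinate-adjacent only after
deletions are not merged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagram import Arc, ArcDiagram


def arcs_cross(a: Arc, b: Arc) -> bool:
    """True iff the two arcs interleave (i_s < i_t < j_s < j_t for the
    earlier-closing arc (i_s, j_s))."""
    if a[1] > b[1]:
        a, b = b, a
    return a[0] < b[0] < a[1] < b[1]


@dataclass(frozen=True)
class StackPartition:
    """Partition of an arc set into maximal parallel chains.

    ``stacks[k]`` lists one chain outermost-first; ``representatives[k]`` is
    its outermost arc (minimal open, maximal close).  Stacks are ordered by
    their representative's closing position, mirroring loop order.
    """

    stacks: tuple[tuple[Arc, ...], ...]
    representatives: tuple[Arc, ...]


def collapse_stacks(arcs) -> StackPartition:
    """Group arcs into maximal parallel chains on their original coordinates."""
    arcset = frozenset(tuple(a) for a in arcs)
    outer_of: dict[Arc, Arc] = {}
    for arc in arcset:
        cur = arc
        while (cur[0] - 1, cur[1] + 1) in arcset:
            cur = (cur[0] - 1, cur[1] + 1)
        outer_of[arc] = cur
    chains: dict[Arc, list[Arc]] = {}
    for arc in arcset:
        chains.setdefault(outer_of[arc], []).append(arc)
    reps = sorted(chains, key=lambda a: a[1])
    return StackPartition(
        stacks=tuple(tuple(sorted(chains[r])) for r in reps),
        representatives=tuple(reps),
    )


def renumber(arcs) -> ArcDiagram:
    """Replace each endpoint by its 1-based rank among all surviving
    endpoints; the result is a sequence-free diagram of length 2 * |arcs|."""
    arclist = [tuple(a) for a in arcs]
    endpoints = sorted(v for a in arclist for v in a)
    rank = {v: k for k, v in enumerate(endpoints, start=1)}
    new_arcs = frozenset((rank[i], rank[j]) for i, j in arclist)
    return ArcDiagram(sequence="", length=2 * len(arclist), arcs=new_arcs)


def _collapse_renumber_fixpoint(
    arc_to_origin: dict[Arc, Arc],
) -> tuple[ArcDiagram, dict[Arc, Arc]]:
    """Alternate stack collapsing and rank renumbering until stable.

    The first collapsing round therefore sees the ORIGINAL coordinates (the
    exact-index parallel predicate); renumbering can make previously gapped
    nested arcs adjacent, so the pair is repeated until nothing merges —
    this is what makes the core and shadow idempotent.  The returned map
    sends each surviving arc to the original arc its chain's outermost
    member descends from.
    """
    current = dict(arc_to_origin)
    while True:
        parts = collapse_stacks(current.keys())
        endpoints = sorted(v for a in parts.representatives for v in a)
        rank = {v: k for k, v in enumerate(endpoints, start=1)}
        renumbered = {
            (rank[i], rank[j]): current[(i, j)] for i, j in parts.representatives
        }
        if renumbered.keys() == current.keys():
            diagram = ArcDiagram(
                sequence="", length=2 * len(renumbered), arcs=frozenset(renumbered)
            )
            return diagram, renumbered
        current = renumbered


def core_of(diagram: ArcDiagram) -> ArcDiagram:
    """Delete unpaired vertices, collapse stacks, renumber (to fixpoint)."""
    return core_with_provenance(diagram)[0]


def core_with_provenance(diagram: ArcDiagram) -> tuple[ArcDiagram, dict[Arc, Arc]]:
    """Core plus a map from each core arc back to the original stack
    representative it came from (used for RRI classification of abstracted
    loops)."""
    return _collapse_renumber_fixpoint({a: a for a in diagram.arcs})


def shadow_of(diagram: ArcDiagram) -> ArcDiagram:
    """Keep only crossing-involved arcs, collapse stacks, renumber.

    Crossing membership is a single pass on the ORIGINAL diagram: an arc
    survives iff it crosses at least one other arc.  (Removing non-crossing
    arcs cannot strand a kept arc — crossing is pairwise between kept arcs —
    and collapsing only extends arcs outward, which preserves crossings.)
    """
    return shadow_with_provenance(diagram)[0]


def shadow_with_provenance(diagram: ArcDiagram) -> tuple[ArcDiagram, dict[Arc, Arc]]:
    arcs = diagram.sorted_arcs
    kept = [
        a for a in arcs
        if any(arcs_cross(a, b) for b in arcs if b != a)
    ]
    return _collapse_renumber_fixpoint({a: a for a in kept})


def is_pseudoknotted(diagram: ArcDiagram) -> bool:
    """True iff some pair of arcs crosses (equivalently: nonempty shadow)."""
    arcs = diagram.sorted_arcs
    return any(
        arcs_cross(arcs[s], arcs[t])
        for s in range(len(arcs))
        for t in range(s + 1, len(arcs))
    )
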