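"""Structural relation matching.

A pattern of M loops occurs in a target of N loops at start s when the
target's relation submatrix over the M CONSECUTIVE loop indices
s..s+M-1 equals the pattern's matrix cell-for-cell.  Windows of consecutive
close-ordered loops realize a restricted arc-preserving-subsequence search:
every arc closing inside the window is retained, while arcs opening outside
it are unconstrained — mirroring the folding process, in which a nucleotide
pairs with one synthesized earlier.

Two independent code paths are provided: :func:`match_pattern` (early-exit
scan with a first-row fast filter) and :func:`brute_force_match` (full
submatrix materialization, no shortcuts), kept separate so each can check
the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .abstractions import core_with_provenance, shadow_with_provenance
from .diagram import ArcDiagram, LoopClass, classify_arc, enumerate_loops
from .errors import EmptyPatternError, StrandBreakError
from .relations import RelationMatrix, build_relation_matrix

Level = Literal["structure", "core", "shadow"]


@dataclass(frozen=True)
class Occurrence:
    """One match: the window of consecutive target loop indices it covers."""

    start: int
    loop_indices: tuple[int, ...]
    classes: tuple[LoopClass, ...] | None = None


@dataclass(frozen=True)
class MatchResult:
    """All occurrences of a pattern in a target, ascending by start."""

    occurrences: tuple[Occurrence, ...]
    pattern_size: int
    target_size: int

    def __len__(self) -> int:
        return len(self.occurrences)

    @property
    def starts(self) -> tuple[int, ...]:
        return tuple(o.start for o in self.occurrences)


def match_pattern(target: RelationMatrix, pattern: RelationMatrix) -> MatchResult:
    """Find every diagonal window of the target equal to the pattern.

    Scans starts 1..N-M+1; per window, the first pattern row is compared
    first (cheap reject), then remaining columns left-to-right with early
    exit on the first mismatch.  A 1-loop pattern matches every loop.
    """
    m, n = pattern.n, target.n
    if m == 0:
        raise EmptyPatternError("pattern has no loops")
    tcodes, pcodes = target._codes, pattern._codes
    found: list[Occurrence] = []
    for s in range(1, n - m + 2):
        base = s - 1
        ok = True
        for b in range(1, m):  # first-row filter: pattern entries (1, b+1)
            if pcodes[0, b] != tcodes[base, base + b]:
                ok = False
                break
        if ok:
            for b in range(2, m):  # remaining columns, top to bottom
                for a in range(1, b):
                    if pcodes[a, b] != tcodes[base + a, base + b]:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            found.append(Occurrence(start=s, loop_indices=tuple(range(s, s + m))))
    return MatchResult(tuple(found), pattern_size=m, target_size=n)


def brute_force_match(target: RelationMatrix, pattern: RelationMatrix) -> MatchResult:
    """Reference matcher: materialize each window's full submatrix and the
    pattern matrix as nested lists, then compare — no early exit, no shared
    code with :func:`match_pattern` beyond the matrix accessor."""
    m, n = pattern.n, target.n
    if m == 0:
        raise EmptyPatternError("pattern has no loops")
    pat = [[pattern[(a, b)] for b in range(a + 1, m + 1)] for a in range(1, m)]
    found = []
    for s in range(1, n - m + 2):
        window = [
            [target[(s + a - 1, s + b - 1)] for b in range(a + 1, m + 1)]
            for a in range(1, m)
        ]
        if window == pat:
            found.append(Occurrence(start=s, loop_indices=tuple(range(s, s + m))))
    return MatchResult(tuple(found), pattern_size=m, target_size=n)


def match_structures(target: ArcDiagram,
                     pattern: ArcDiagram | RelationMatrix,
                     level: Level = "structure",
                     strand_break: int | None = None) -> MatchResult:
    """End-to-end matching of two structures at a chosen abstraction level.

    Both target and pattern are abstracted with the same ``level``
    (a pattern supplied directly as a :class:`RelationMatrix` bypasses
    abstraction), loops are enumerated, matrices built and matched.  With
    ``strand_break`` set, each occurrence is annotated with the RRI class of
    every loop in its window; for core/shadow levels the class of an
    abstract loop is that of the stack-representative arc it descends from,
    judged against the break on ORIGINAL coordinates.
    """
    if level == "structure":
        abstract, provenance = target, {a: a for a in target.arcs}
    elif level == "core":
        abstract, provenance = core_with_provenance(target)
    elif level == "shadow":
        abstract, provenance = shadow_with_provenance(target)
    else:
        raise ValueError(f"unknown abstraction level {level!r}")

    tloops = enumerate_loops(abstract)
    tmat = build_relation_matrix(tloops)

    if isinstance(pattern, RelationMatrix):
        pmat = pattern
    else:
        if level == "structure":
            pabs = pattern
        elif level == "core":
            pabs = core_with_provenance(pattern)[0]
        else:
            pabs = shadow_with_provenance(pattern)[0]
        ploops = enumerate_loops(pabs)
        if not ploops:
            raise EmptyPatternError(
                f"pattern has no loops at level {level!r} "
                "(e.g. the shadow of a pseudoknot-free structure is empty)"
            )
        pmat = build_relation_matrix(ploops)

    result = match_pattern(tmat, pmat)
    if strand_break is None:
        return result

    if not 1 <= strand_break < target.length:
        raise StrandBreakError(
            f"strand break {strand_break} outside 1..{target.length - 1}"
        )
    loop_class = [
        classify_arc(provenance[(lp.open, lp.close)], strand_break) for lp in tloops
    ]
    annotated = tuple(
        Occurrence(
            start=o.start,
            loop_indices=o.loop_indices,
            classes=tuple(loop_class[k - 1] for k in o.loop_indices),
        )
        for o in result.occurrences
    )
    return MatchResult(annotated, result.pattern_size, result.target_size)
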