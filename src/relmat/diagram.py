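"""Arc-diagram data model, Bpseq I/O and loop enumeration.

An RNA secondary structure — or an RNA-RNA interaction written as one
concatenated strand — is modelled as an *arc diagram*: vertices 1..length on
a backbone line, plus a set of arcs (i, j) with i < j, one per base pair,
drawn in the upper half-plane.  Each arc determines a *loop*.  Loops are
enumerated by strictly ascending closing position; that order is what fixes
the rows and columns of the relation matrix downstream, so it is the single
most load-bearing convention in the package.

Coordinates are 1-based closed intervals throughout, matching the Bpseq
format.  Abstractions (cores, shadows) are arc diagrams with an empty
sequence; only they are allowed to contain adjacent-endpoint arcs
(j == i + 1), since those arise naturally from collapsing and renumbering.
Diagrams carrying real nucleotides keep the no-contiguous-pair rule: a base
cannot pair with its backbone neighbour.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import (
    ContiguousPairingError,
    DuplicatePositionError,
    FieldFormatError,
    InvalidDiagramError,
    MissingPositionError,
    NonReciprocalPairingError,
    SelfPairingError,
    StrandBreakError,
)

logger = logging.getLogger("relmat")

Arc = tuple[int, int]

#: Letters accepted without a warning: the four RNA bases plus IUPAC
#: ambiguity codes (and T, common in database exports).
IUPAC_LETTERS = frozenset("ACGUTNRYSWKMBDHV")
CANONICAL_LETTERS = frozenset("ACGU")


@dataclass(frozen=True)
class ArcDiagram:
    """An arc-annotated sequence D = (omega, B).

    Parameters
    ----------
    sequence:
        Residue letters, one per vertex, or the empty string for
        abstractions (cores and shadows carry no nucleotides).
    length:
        Number of backbone vertices.
    arcs:
        Base pairs as 1-based (i, j) tuples with i < j; at most one arc per
        vertex.
    """

    sequence: str
    length: int
    arcs: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        if self.length < 0:
            raise InvalidDiagramError(f"negative length {self.length}")
        if self.sequence and len(self.sequence) != self.length:
            raise InvalidDiagramError(
                f"sequence of {len(self.sequence)} letters on {self.length} vertices"
            )
        seen: set[int] = set()
        for i, j in sorted(self.arcs):
            if not (isinstance(i, int) and isinstance(j, int)):
                raise InvalidDiagramError(f"non-integer arc endpoints ({i}, {j})")
            if not (1 <= i < j <= self.length):
                raise InvalidDiagramError(
                    f"arc ({i}, {j}) outside 1..{self.length} or unordered"
                )
            if self.sequence and j == i + 1:
                raise InvalidDiagramError(
                    f"arc ({i}, {j}) pairs backbone neighbours"
                )
            for v in (i, j):
                if v in seen:
                    raise InvalidDiagramError(f"vertex {v} belongs to two arcs")
                seen.add(v)

    @property
    def sorted_arcs(self) -> list[Arc]:
        """Arcs sorted by ascending closing position (= loop order)."""
        return sorted(self.arcs, key=lambda a: a[1])

    @property
    def paired(self) -> frozenset[int]:
        return frozenset(v for a in self.arcs for v in a)

    def partner_of(self, position: int) -> int:
        """Partner of ``position``, or 0 if unpaired."""
        for i, j in self.arcs:
            if i == position:
                return j
            if j == position:
                return i
        return 0


class Loop(NamedTuple):
    """One arc (open, close) with its enumeration rank (1-based)."""

    open: int
    close: int
    index: int


class LoopClass(enum.Enum):
    """Origin of a loop in an RNA-RNA interaction diagram."""

    INTRA1 = "intra1"  # entirely on molecule 1 (close <= strand break)
    INTRA2 = "intra2"  # entirely on molecule 2 (open > strand break)
    INTER = "inter"    # interaction arc spanning the strand break


@dataclass(frozen=True)
class RriAnnotation:
    """Strand-break bookkeeping for an RNA-RNA interaction.

    ``strand_break`` is the last vertex of molecule 1; molecule 2 occupies
    strand_break+1..length.  ``loop_classes`` maps each loop index to its
    :class:`LoopClass`.
    """

    strand_break: int
    loop_classes: dict[int, LoopClass]


def classify_arc(arc: Arc, strand_break: int) -> LoopClass:
    """Class of a single arc relative to a strand break."""
    i, j = arc
    if i <= strand_break < j:
        return LoopClass.INTER
    return LoopClass.INTRA1 if j <= strand_break else LoopClass.INTRA2


def parse_bpseq(source: str | os.PathLike) -> ArcDiagram:
    """Read a Bpseq file (or literal Bpseq text) into an :class:`ArcDiagram`.

    Data lines hold three whitespace-separated columns: position, base,
    partner (0 = unpaired), positions exactly 1..length ascending.  Blank
    lines and lines starting with '#' are skipped; any other malformed line
    is fatal.  Bases outside A/C/G/U are tolerated with a logged warning.
    """
    if isinstance(source, os.PathLike):
        text = Path(source).read_text()
    elif "\n" not in source and os.path.exists(source):
        text = Path(source).read_text()
    else:
        text = source

    entries: dict[int, tuple[str, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise FieldFormatError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            pos = int(fields[0])
            partner = int(fields[2])
        except ValueError as exc:
            raise FieldFormatError(f"line {lineno}: non-integer field: {line!r}") from exc
        base = fields[1]
        if len(base) != 1 or not base.isalpha():
            raise FieldFormatError(f"line {lineno}: base field {base!r} is not a letter")
        if pos in entries:
            raise DuplicatePositionError(f"line {lineno}: position {pos} repeated")
        entries[pos] = (base.upper(), partner)

    n = len(entries)
    if sorted(entries) != list(range(1, n + 1)):
        missing = sorted(set(range(1, n + 1)) - set(entries))
        raise MissingPositionError(
            f"positions are not exactly 1..{n}: missing/extra around {missing or sorted(entries)[-3:]}"
        )

    odd = {b for b, _ in entries.values() if b not in CANONICAL_LETTERS}
    if odd:
        logger.warning("non-AUGC bases tolerated: %s", "".join(sorted(odd)))

    arcs: set[Arc] = set()
    for pos in range(1, n + 1):
        _, partner = entries[pos]
        if partner == 0:
            continue
        if partner == pos:
            raise SelfPairingError(f"position {pos} pairs with itself")
        if not (1 <= partner <= n):
            raise NonReciprocalPairingError(
                f"position {pos} names partner {partner} outside 1..{n}"
            )
        if abs(partner - pos) == 1:
            raise ContiguousPairingError(
                f"position {pos} pairs with backbone neighbour {partner}"
            )
        if entries[partner][1] != pos:
            raise NonReciprocalPairingError(
                f"position {pos} says {partner}, but {partner} says {entries[partner][1]}"
            )
        arcs.add((min(pos, partner), max(pos, partner)))

    sequence = "".join(entries[p][0] for p in range(1, n + 1))
    return ArcDiagram(sequence=sequence, length=n, arcs=frozenset(arcs))


def write_bpseq(diagram: ArcDiagram, header: str | None = None) -> str:
    """Serialize a diagram to canonical Bpseq text.

    Abstractions (empty sequence) are emitted with 'N' residues.  Note that
    abstractions may contain adjacent-endpoint arcs, which the Bpseq parser
    rejects by design; the JSON arc-list form is the lossless route for
    those (see :mod:`relmat.abstractions`).
    """
    partner = {p: 0 for p in range(1, diagram.length + 1)}
    for i, j in diagram.arcs:
        partner[i] = j
        partner[j] = i
    seq = diagram.sequence or "N" * diagram.length
    lines = [] if header is None else [f"# {header}"]
    lines += [f"{p} {seq[p - 1]} {partner[p]}" for p in range(1, diagram.length + 1)]
    return "\n".join(lines) + "\n"


def enumerate_loops(diagram: ArcDiagram) -> list[Loop]:
    """Enumerate loops by strictly ascending closing position.

    Closing positions are unique (each vertex sits on at most one arc), so
    the order — and hence the loop indexing L1..LN — is total and
    deterministic.
    """
    return [Loop(i, j, s) for s, (i, j) in enumerate(diagram.sorted_arcs, start=1)]


def annotate_rri(diagram: ArcDiagram, strand_break: int) -> RriAnnotation:
    """Classify every loop of a concatenated-duplex diagram.

    A loop is INTER iff its arc spans the strand break
    (open <= strand_break < close); otherwise it lies entirely on molecule 1
    (INTRA1) or molecule 2 (INTRA2).
    """
    if not 1 <= strand_break < diagram.length:
        raise StrandBreakError(
            f"strand break {strand_break} outside 1..{diagram.length - 1}"
        )
    classes = {
        loop.index: classify_arc((loop.open, loop.close), strand_break)
        for loop in enumerate_loops(diagram)
    }
    return RriAnnotation(strand_break=strand_break, loop_classes=classes)


def arcs_from_json(items: Iterable[Iterable[int]], length: int | None = None,
                   sequence: str = "") -> ArcDiagram:
    """Build a diagram from a JSON-style arc list ``[[i, j], ...]``."""
    arcs = frozenset((int(i), int(j)) for i, j in items)
    if length is None:
        length = max((j for _, j in arcs), default=0)
    return ArcDiagram(sequence=sequence, length=length, arcs=arcs)
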