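"""Loop-pair classification and the relation matrix.

For two loops L_s = (i_s, j_s) and L_t = (i_t, j_t) with j_s < j_t (s < t in
enumeration order) exactly one of three relations holds:

    concatenation  L_s o L_t :  i_s < j_s < i_t < j_t   (disjoint, L_s left)
    nesting        L_s n L_t :  i_t < i_s < j_s < j_t   (L_s inside L_t)
    crossing       L_s x L_t :  i_s < i_t < j_s < j_t   (intervals interleave)

Collecting the relation of every ordered pair into a strict upper-triangular
N x N array gives the structure's *relation matrix*, the object on which
structural pattern matching operates.  Crossing is the signature of a
pseudoknot: a pseudoknot-free structure has a cross-free matrix.
"""

from __future__ import annotations

import enum
import json
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .diagram import Loop, LoopClass, RriAnnotation
from .errors import LoopPairError, MatrixFormatError


class Relation(enum.Enum):
    """The three possible relations between two loops."""

    CONCAT = "o"
    NEST = "n"
    CROSS = "x"

    @property
    def glyph(self) -> str:
        return {"o": "⊙", "n": "⋒", "x": "⨯"}[self.value]

    def __str__(self) -> str:  # serialization character
        return self.value


_CODE = {Relation.CONCAT: 1, Relation.NEST: 2, Relation.CROSS: 3}
_RELATION = {v: k for k, v in _CODE.items()}
_BY_CHAR = {r.value: r for r in Relation}


def classify_relation(a: Loop | Sequence[int], b: Loop | Sequence[int]) -> Relation:
    """Relation of the earlier-closing loop ``a`` to ``b``.

    Requires a.close < b.close and four distinct endpoints.
    """
    ia, ja = a[0], a[1]
    ib, jb = b[0], b[1]
    if ja >= jb:
        raise LoopPairError(f"loops ({ia},{ja}), ({ib},{jb}) not in closing order")
    if len({ia, ja, ib, jb}) != 4:
        raise LoopPairError(f"loops ({ia},{ja}), ({ib},{jb}) share an endpoint")
    if ja < ib:
        return Relation.CONCAT
    if ib < ia:
        return Relation.NEST
    return Relation.CROSS


class RelationMatrix:
    """Strict upper-triangular N x N array of :class:`Relation` symbols.

    Entries are addressed by 1-based loop-index pairs ``m[s, t]`` with
    s < t.  ``loop_labels`` optionally records original loop indices after a
    row/column permutation (see :func:`permute_rri_matrix`); labels are
    bookkeeping metadata and do not enter equality.
    """

    __slots__ = ("n", "_codes", "loop_labels")

    def __init__(self, n: int, codes: np.ndarray | None = None,
                 loop_labels: tuple[int, ...] | None = None) -> None:
        if n < 0:
            raise MatrixFormatError(f"negative loop count {n}")
        self.n = n
        self._codes = np.zeros((n, n), dtype=np.uint8) if codes is None else codes
        if self._codes.shape != (n, n):
            raise MatrixFormatError("code array shape does not match n")
        self.loop_labels = loop_labels

    @classmethod
    def from_entries(cls, n: int,
                     entries: Mapping[tuple[int, int], Relation]) -> "RelationMatrix":
        expected = n * (n - 1) // 2
        if len(entries) != expected:
            raise MatrixFormatError(
                f"{len(entries)} entries for {n} loops; expected {expected}"
            )
        m = cls(n)
        for (s, t), rel in entries.items():
            if not (1 <= s < t <= n):
                raise MatrixFormatError(f"entry ({s}, {t}) outside strict upper triangle")
            m._codes[s - 1, t - 1] = _CODE[Relation(rel)]
        return m

    def __getitem__(self, key: tuple[int, int]) -> Relation:
        s, t = key
        if not (1 <= s < t <= self.n):
            raise MatrixFormatError(f"({s}, {t}) outside strict upper triangle of N={self.n}")
        return _RELATION[int(self._codes[s - 1, t - 1])]

    def items(self) -> Iterator[tuple[tuple[int, int], Relation]]:
        """Entries in ascending lexicographic (s, t) order."""
        for s in range(1, self.n + 1):
            for t in range(s + 1, self.n + 1):
                yield (s, t), _RELATION[int(self._codes[s - 1, t - 1])]

    @property
    def n_entries(self) -> int:
        return self.n * (self.n - 1) // 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationMatrix):
            return NotImplemented
        return self.n == other.n and bool(np.array_equal(self._codes, other._codes))

    def __hash__(self) -> int:
        return hash((self.n, self._codes.tobytes()))

    def __repr__(self) -> str:
        return f"RelationMatrix(n={self.n})"


def build_relation_matrix(loops: Sequence[Loop]) -> RelationMatrix:
    """Relation matrix of loops enumerated by ascending close position.

    O(N^2): one classification per ordered pair.
    """
    closes = [lp.close for lp in loops]
    if closes != sorted(closes) or len(set(closes)) != len(closes):
        raise LoopPairError("loops must be enumerated by strictly ascending close")
    n = len(loops)
    m = RelationMatrix(n)
    codes = m._codes
    for s in range(n):
        a = loops[s]
        for t in range(s + 1, n):
            codes[s, t] = _CODE[classify_relation(a, loops[t])]
    return m


_BLOCK_RANK = {LoopClass.INTRA1: 0, LoopClass.INTER: 1, LoopClass.INTRA2: 2}


def permute_rri_matrix(matrix: RelationMatrix,
                       annotation: RriAnnotation) -> RelationMatrix:
    """Reorder rows/columns into INTRA1, INTER, INTRA2 blocks.

    The permutation is stable within blocks, so applying it twice is a
    no-op.  Entries travel with their loop pair: the relation recorded for
    original loops (s, t) is unchanged, only its matrix position moves.
    ``loop_labels`` of the result records original loop indices per row.
    """
    labels = matrix.loop_labels or tuple(range(1, matrix.n + 1))
    try:
        ranks = [_BLOCK_RANK[annotation.loop_classes[lab]] for lab in labels]
    except KeyError as exc:
        raise MatrixFormatError(f"annotation missing loop index {exc.args[0]}") from exc
    order = sorted(range(matrix.n), key=lambda k: (ranks[k], k))  # stable
    pos_of = {labels[k]: k for k in range(matrix.n)}
    new_labels = tuple(labels[k] for k in order)
    out = RelationMatrix(matrix.n, loop_labels=new_labels)
    for p in range(matrix.n):
        for q in range(p + 1, matrix.n):
            a, b = pos_of[new_labels[p]], pos_of[new_labels[q]]
            out._codes[p, q] = matrix._codes[min(a, b), max(a, b)]
    return out


def block_sizes(matrix: RelationMatrix, annotation: RriAnnotation) -> tuple[int, int, int]:
    """(|INTRA1|, |INTER|, |INTRA2|) loop counts under an annotation."""
    counts = [0, 0, 0]
    for cls in annotation.loop_classes.values():
        counts[_BLOCK_RANK[cls]] += 1
    return tuple(counts)  # type: ignore[return-value]


def serialize_matrix(matrix: RelationMatrix) -> str:
    """Canonical TSV: header ``N <n>`` then one ``s<TAB>t<TAB>c`` line per
    entry in ascending (s, t) order, c in {o, n, x}."""
    lines = [f"N {matrix.n}"]
    lines += [f"{s}\t{t}\t{rel.value}" for (s, t), rel in matrix.items()]
    return "\n".join(lines) + "\n"


def deserialize_matrix(text: str) -> RelationMatrix:
    """Inverse of :func:`serialize_matrix`; rejects malformed input loudly."""
    lines = [ln for ln in (raw.strip() for raw in text.splitlines())
             if ln and not ln.startswith("#")]
    if not lines or not lines[0].startswith("N"):
        raise MatrixFormatError("missing 'N <count>' header")
    head = lines[0].split()
    if len(head) != 2:
        raise MatrixFormatError(f"malformed header {lines[0]!r}")
    try:
        n = int(head[1])
    except ValueError as exc:
        raise MatrixFormatError(f"non-integer loop count {head[1]!r}") from exc
    entries: dict[tuple[int, int], Relation] = {}
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) != 3:
            raise MatrixFormatError(f"malformed entry line {ln!r}")
        try:
            s, t = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise MatrixFormatError(f"non-integer indices in {ln!r}") from exc
        if fields[2] not in _BY_CHAR:
            raise MatrixFormatError(f"unknown relation symbol {fields[2]!r}")
        if not (1 <= s < t <= n):
            raise MatrixFormatError(f"entry ({s}, {t}) outside strict upper triangle")
        if (s, t) in entries:
            raise MatrixFormatError(f"duplicate entry ({s}, {t})")
        entries[(s, t)] = _BY_CHAR[fields[2]]
    return RelationMatrix.from_entries(n, entries)


def matrix_to_json(matrix: RelationMatrix) -> str:
    """JSON form: ``{"n": N, "entries": [[s, t, "x"], ...], "labels": [...]}``."""
    doc = {
        "n": matrix.n,
        "entries": [[s, t, rel.value] for (s, t), rel in matrix.items()],
    }
    if matrix.loop_labels is not None:
        doc["labels"] = list(matrix.loop_labels)
    return json.dumps(doc)


def matrix_from_json(text: str) -> RelationMatrix:
    try:
        doc = json.loads(text)
        n = int(doc["n"])
        raw = doc["entries"]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise MatrixFormatError(f"malformed matrix JSON: {exc}") from exc
    entries: dict[tuple[int, int], Relation] = {}
    for item in raw:
        s, t, c = item
        if c not in _BY_CHAR:
            raise MatrixFormatError(f"unknown relation symbol {c!r}")
        if (int(s), int(t)) in entries:
            raise MatrixFormatError(f"duplicate entry ({s}, {t})")
        entries[(int(s), int(t))] = _BY_CHAR[c]
    m = RelationMatrix.from_entries(n, entries)
    if "labels" in doc:
        m.loop_labels = tuple(int(x) for x in doc["labels"])
    return m
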