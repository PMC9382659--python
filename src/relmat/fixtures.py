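"""Bundled worked-example fixtures.

Small classroom-scale structures used throughout the tests, the examples
and the documentation:

* ``pseudoknotted_example`` — a 28-nt structure with 8 arcs, two helices
  and one crossing pair of helices (a pseudoknotted motif).
* ``interaction_example`` — a 19-nt concatenated duplex (strand break after
  position 9) whose three helices are one intramolecular stem per molecule
  plus an intermolecular kissing interaction.
* ``nine_loop_example`` — a 28-vertex diagram with nine loops, convenient
  for exercising the full 36-entry relation matrix.
* ``demo_structure_matrix`` / ``demo_pattern_matrix`` — a 6-loop structure
  matrix containing the 3-loop pattern matrix twice, the canonical matching
  demonstration.
"""

from __future__ import annotations

from importlib.resources import files

from .diagram import ArcDiagram, parse_bpseq
from .relations import RelationMatrix, deserialize_matrix

#: Strand break of the interaction example: molecule 1 is positions 1..9.
INTERACTION_STRAND_BREAK = 9


def fixture_text(name: str) -> str:
    """Raw text of a bundled data file."""
    return (files("relmat") / "data" / name).read_text()


def pseudoknotted_example() -> ArcDiagram:
    return parse_bpseq(fixture_text("pk28.bpseq"))


def interaction_example() -> ArcDiagram:
    return parse_bpseq(fixture_text("duplex19.bpseq"))


def nine_loop_example() -> ArcDiagram:
    return parse_bpseq(fixture_text("nineloops28.bpseq"))


def demo_structure_matrix() -> RelationMatrix:
    return deserialize_matrix(fixture_text("demo_structure.tsv"))


def demo_pattern_matrix() -> RelationMatrix:
    return deserialize_matrix(fixture_text("demo_pattern.tsv"))
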