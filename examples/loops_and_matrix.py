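"""Enumerate the loops of a structure and build its relation matrix.

Every arc (i, j) of a secondary structure determines a loop; loops are
indexed by ascending closing position.  Each ordered loop pair is in
exactly one of three relations — concatenation (o), nesting (n) or
crossing (x) — and the strict upper-triangular matrix of those symbols
characterizes the structure's topology.
"""

from relmat import build_relation_matrix, enumerate_loops, fixtures, serialize_matrix

diagram = fixtures.nine_loop_example()
loops = enumerate_loops(diagram)
print(f"{len(loops)} loops on {diagram.length} vertices:")
for loop in loops:
    print(f"  L{loop.index} = ({loop.open}, {loop.close})")

matrix = build_relation_matrix(loops)
print(f"\nrelation matrix: N = {matrix.n}, {matrix.n_entries} entries")
print(serialize_matrix(matrix))
# Each line "s t c" says loop L_s stands in relation c to loop L_t;
# an N-loop structure always has exactly N(N-1)/2 such relations.
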