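"""Analyze an RNA-RNA interaction encoded as one concatenated diagram.

A duplex of two molecules is written as a single Bpseq file plus a strand
break: molecule 1 occupies positions 1..break, molecule 2 the rest.  Each
loop is then intramolecular (INTRA1/INTRA2) or an interaction loop (INTER,
its arc spans the break), and the relation matrix can be block-permuted so
the three classes form contiguous row/column blocks.
"""

from relmat import (
    annotate_rri,
    block_sizes,
    build_relation_matrix,
    enumerate_loops,
    fixtures,
    permute_rri_matrix,
    serialize_matrix,
)

duplex = fixtures.interaction_example()
break_pos = fixtures.INTERACTION_STRAND_BREAK
annotation = annotate_rri(duplex, break_pos)

print(f"duplex: {duplex.length} nt, strand break after position {break_pos}")
for loop in enumerate_loops(duplex):
    cls = annotation.loop_classes[loop.index]
    print(f"  L{loop.index} = ({loop.open}, {loop.close})  {cls.value}")

matrix = build_relation_matrix(enumerate_loops(duplex))
print(f"\nblock sizes (intra1, inter, intra2): {block_sizes(matrix, annotation)}")
permuted = permute_rri_matrix(matrix, annotation)
print(f"row order after permutation (original loop indices): {permuted.loop_labels}")
print(serialize_matrix(permuted))
# entries travel with their loops: the relation between two given loops is
# unchanged, only its position in the matrix moves
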