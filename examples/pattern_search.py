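"""Find every occurrence of a structural pattern inside a structure.

A pattern of M loops occurs wherever a window of M CONSECUTIVE target
loops induces a relation submatrix equal to the pattern's matrix.  This
realizes a restricted arc-preserving-subsequence search: arcs closing
inside the window are all retained, arcs opening outside it are free —
matching how a folding chain pairs each base with an earlier one.
"""

from relmat import fixtures, match_pattern, match_structures, realize_matrix

structure = fixtures.demo_structure_matrix()   # 6 loops
pattern = fixtures.demo_pattern_matrix()       # 3 loops: x, x over a nest

result = match_pattern(structure, pattern)
print(f"pattern of {result.pattern_size} loops in target of {result.target_size}:")
for occ in result.occurrences:
    print(f"  occurrence at loops {occ.loop_indices}")
# two occurrences: loop windows (1,2,3) and (4,5,6)

# the same search from concrete structures: realize both matrices as
# arc diagrams, then match at the plain-structure level
target_d = realize_matrix(structure)
pattern_d = realize_matrix(pattern)
res2 = match_structures(target_d, pattern_d, level="structure")
print(f"via realized diagrams: {len(res2)} occurrences (same windows)")
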