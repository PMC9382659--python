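"""Abstract a pseudoknotted structure into its core and its shadow.

The core deletes unpaired vertices and collapses each helix (maximal run
of stacked arcs) to one arc — an intermediate-scale view of the topology.
The shadow additionally keeps only arcs involved in a crossing: it is the
pseudoknot skeleton, and it is empty exactly when the structure is
pseudoknot-free.
"""

from relmat import core_of, fixtures, is_pseudoknotted, shadow_of

diagram = fixtures.pseudoknotted_example()
print(f"structure: {diagram.length} nt, {len(diagram.arcs)} arcs")
print(f"pseudoknotted: {is_pseudoknotted(diagram)}")

core = core_of(diagram)
print(f"core:   {sorted(core.arcs)}")
# six arcs: one per helix of the original structure

shadow = shadow_of(diagram)
print(f"shadow: {sorted(shadow.arcs)}")
# {(1,3), (2,4)} is the minimal crossing pair: the structure's only
# pseudoknot involves two helices that interleave
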