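# relmat

Relation matrices and structural pattern matching for RNA secondary
structures — including arbitrary pseudoknots — and RNA–RNA interactions.

## The problem

RNA function tracks structure, and functional RNA families conserve their
secondary structure far better than their sequence, so locating a known
*structural* motif inside a larger structure is a recurring task.  Most
exact substructure-search methods either exclude pseudoknots or face
NP-hard arc-annotated-sequence problems.  `relmat` takes a different route:
it reduces a structure of any topology to a small combinatorial
fingerprint — the **relation matrix** — in which pattern search becomes
exact submatrix location, polynomial in the number of base pairs.

## The formalism

A secondary structure is an **arc diagram** `D = (ω, B)`: vertices
`1..ℓ` on a backbone line and arcs `(i, j) ∈ B`, `i < j`, one per base
pair, with each vertex on at most one arc.  Every arc determines a
**loop**; loops `L_1..L_N` are enumerated by strictly ascending closing
position.  For `s < t` (so `j_s < j_t`) exactly one of three relations
holds between `L_s = (i_s, j_s)` and `L_t = (i_t, j_t)`:

| relation | symbol | condition |
|---|---|---|
| concatenation | `L_s ⊙ L_t` | `i_s < j_s < i_t < j_t` |
| nesting | `L_s ⋒ L_t` | `i_t < i_s < j_s < j_t` |
| crossing | `L_s ⨯ L_t` | `i_s < i_t < j_s < j_t` |

Crossing is the signature of a pseudoknot.  The strict upper-triangular
N×N array `a_st` of these symbols is the structure's relation matrix,
computable in `O(N²)`.

Two abstractions coarsen a diagram while staying inside the same
formalism.  The **core** deletes unpaired vertices and collapses each
helix (maximal chain of stacked arcs `(i, j), (i+1, j−1), …`) to a single
arc, then renumbers.  The **shadow** keeps only arcs that cross at least
one other arc before collapsing and renumbering: it is the pseudoknot
skeleton, empty iff the structure is pseudoknot-free.

A pattern of `M` loops **occurs** in a target of `N` loops at start `s`
when the target submatrix over the `M` *consecutive* loop indices
`s..s+M−1` equals the pattern matrix cell-for-cell.  Windows of
consecutive close-ordered loops implement a restricted
arc-preserving-subsequence search: every arc closing inside the window is
retained, while arcs opening outside it are unconstrained — mirroring the
folding process, in which each base pairs with one synthesized earlier.
For RNA–RNA interactions, the duplex is written as one concatenated
diagram with a strand break; loops are classed as intramolecular
(`INTRA1`, `INTRA2`) or interaction loops (`INTER`, arc spans the break),
and the matrix can be block-permuted by class.

## Worked example

```python
from relmat import (fixtures, enumerate_loops, build_relation_matrix,
                    shadow_of, core_of, match_pattern)

pk = fixtures.pseudoknotted_example()     # 28-nt structure, 8 arcs
print(sorted(shadow_of(pk).arcs))         # [(1, 3), (2, 4)]
print(sorted(core_of(pk).arcs))           # [(1, 2), (3, 4), (5, 11), (6, 7), (8, 12), (9, 10)]

res = match_pattern(fixtures.demo_structure_matrix(),
                    fixtures.demo_pattern_matrix())
print([o.loop_indices for o in res.occurrences])   # [(1, 2, 3), (4, 5, 6)]
```

The shadow `{(1,3), (2,4)}` is the minimal crossing pair — the structure's
single pseudoknot.  The core's six arcs are its six helices.  The 3-loop
pattern (two crossings over a nested pair) occurs twice in the 6-loop
demonstration structure, at loop windows 1–3 and 4–6.

The same operations are available from the shell:

```bash
relmat matrix structure.bpseq --level shadow        # N 2 / 1 2 x
relmat match --target structure.tsv --pattern pattern.tsv
relmat generate --length 30 --arcs 8 --crossing-bias 1.0 --seed 5
```

Each script in `examples/` demonstrates one capability end to end
(loop enumeration, abstractions, pattern search, RNA–RNA interaction
blocks, random generation / matrix realization).

## Layout

```
src/relmat/     diagram.py (Bpseq I/O, loops, RRI), abstractions.py,
                relations.py, matching.py, synthetic.py, cli.py,
                fixtures.py + data/
tests/          unit + property suites, acceptance checks
examples/       one narrative script per capability
docs/methods.md model, conventions, numerical choices, limitations
```
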