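# Methods

## Model

`relmat` operates on arc diagrams `D = (ω, B)`: an ordered vertex set
`1..ℓ` (the backbone, 5'→3'), a residue string `ω` (empty for
abstractions), and a set `B` of arcs `(i, j)`, `i < j`, one per base pair.
The modelling assumptions are exactly those of secondary structure with
arbitrary pseudoknots:

- each vertex lies on at most one arc (no base triples);
- a base never pairs with its backbone neighbour (`j > i + 1`) when real
  nucleotides are present;
- pairing chemistry is *not* checked — the formalism is purely
  topological, so G–C, A–U, wobble and even non-canonical annotations are
  all treated alike.

Every arc determines a loop.  Loops are enumerated by strictly ascending
closing position (closing positions are unique because vertices have arc
degree ≤ 1), and all downstream objects inherit this order.  For two loops
with `j_s < j_t` exactly one of concatenation (`i_s < j_s < i_t < j_t`),
nesting (`i_t < i_s`) or crossing (`i_s < i_t < j_s`) holds; the proof is
a case split on where `i_t` falls relative to `(i_s, j_s)`.  The relation
matrix collects these symbols over the strict upper triangle; it is
invariant under any order-preserving relabelling of vertex coordinates,
which is what makes the abstractions below compatible with it.

## Abstractions

Two arcs are *stacked* (parallel) when immediately adjacent on both sides:
`(i, j)` and `(i+1, j−1)`.  Maximal stacked chains are helices; collapsing
replaces a chain by its outermost member.  The **core** is: collapse
helices, delete unpaired vertices (implicit — only arc endpoints survive),
renumber endpoints by rank.  The **shadow** first discards every arc that
crosses no other arc, then collapses and renumbers.

Two conventions deserve justification:

- **Fixpoint collapsing.**  Renumbering can make two nested arcs adjacent
  that were separated only by unpaired vertices (e.g. `{(1,10), (3,8)}`
  renumbers to `{(1,4), (2,3)}`).  A single collapse pass would therefore
  produce cores that a second application still shrinks.  `relmat`
  alternates collapse and renumber until stable, which makes `core_of` and
  `shadow_of` idempotent — an abstraction applied to its own output is the
  identity, as an abstraction should be.  The first pass still evaluates
  the stacking predicate on the original coordinates.  All bundled worked
  examples reach the fixpoint in one pass.
- **Representative choice is irrelevant.**  Collapsing to the innermost
  instead of the outermost member of a helix yields the identical
  renumbered diagram (relations depend only on endpoint order, which is
  the same for every member of a chain); the property suite asserts this
  on random inputs.

A diagram is pseudoknotted iff some arc pair crosses, iff its shadow is
nonempty; cross-free matrices, empty shadows and the pairwise crossing
scan are asserted equivalent in the tests.

Abstractions carry no residues, and their renumbered arcs may be
adjacent-endpoint pairs such as `(1, 2)`.  They can be written as Bpseq
(with `N` residues) for display, but the Bpseq *parser* enforces the
no-neighbour-pairing rule of real molecules, so the lossless serialization
for abstractions is the JSON arc list (`relmat abstract --format json`).

## Matching

An occurrence of an `M`-loop pattern in an `N`-loop target is a window of
`M` consecutive target loop indices whose induced submatrix equals the
pattern matrix.  Consecutive-window semantics realize a restricted
arc-preserving-subsequence search: a window of close-ordered loops retains
every arc closing inside it, while arcs opening outside are unconstrained.
General (non-contiguous) arc-preserving subsequence search is NP-hard with
pseudoknots and is deliberately out of scope; the window restriction also
has a folding rationale, since each base pairs with an earlier-synthesized
one.

Two independent implementations exist: the production matcher (per-window
first-row filter, then column-major comparison with early exit) and a
brute-force oracle that materializes every window fully and compares
cell-by-cell with no shortcuts.  Their equivalence is asserted on the
bundled examples and on 1,000 seeded random matrix pairs (N ≤ 40, M ≤ 8),
half of which have the pattern planted as a copied window so that positive
matches are well exercised.  Matching cost is `O((N−M)·M²)` worst case on
top of the `O(N²)` matrix build; a smoke test checks the measured growth
of the build over N ∈ {50, 100, 200, 400} stays in the quadratic range,
with a threefold allowance for timer noise.

For RNA–RNA interactions the duplex is one concatenated diagram plus a
strand break `n₁` (molecule 1 = positions `1..n₁`).  A loop is INTER iff
its arc spans the break (`i ≤ n₁ < j`).  The block permutation orders
rows/columns INTRA1, INTER, INTRA2, stably within blocks — a deterministic
convention chosen for reproducibility; entries travel with their loop
pair, so the relation recorded for two given loops is permutation
invariant.  When matching at core/shadow level with a strand break, an
abstract loop inherits the class of the helix representative it descends
from, judged on original coordinates.

## Synthetic data

`generate_diagram(length, n_arcs, crossing_bias, seed)` samples valid
diagrams; all randomness flows through one `random.Random(seed)`-derived
stream, so identical configs give identical output.  Defaults used across
the test suite: lengths 6–60 vertices, up to `length/2 − 1` arcs, biases
drawn from {0, ¼, ½, ¾, 1} — classroom-scale structures that keep
property suites exhaustive-feeling yet fast, not thermodynamic samples.

- `crossing_bias = 0` must yield a pseudoknot-free diagram.  Feasibility
  is exact: `k` non-crossing, non-contiguous arcs fit iff
  `length ≥ 2k + 1` (every innermost arc must enclose an unpaired
  vertex, and a nested chain needs only one).  Construction is recursive
  and feasibility-checked at every choice, so it never dead-ends.
- `crossing_bias = 1` forces every arc after the first to cross an
  existing one when possible, and retries until the result is
  pseudoknotted whenever `n_arcs ≥ 2`.
- Intermediate biases mark each arc "must cross" with probability equal
  to the bias and place arcs by randomized backtracking under a node
  budget; dense configurations relax the non-forced-arcs-stay-non-crossing
  preference after a few failed attempts rather than failing.

What the generator does **not** emulate: base-pairing chemistry (residues
are uniform random letters), helix length distributions, loop-size
energetics, or the long-range correlation structure of real ribosomal
RNAs.  Green property suites therefore certify the combinatorial
contracts of the formalism, not biological realism of inputs.

`realize_matrix` inverts the fingerprint: given a relation matrix it finds
a diagram reproducing it, or proves none exists.  Since only the relative
order of the `2N` endpoints matters, the search runs over token sequences:
closing tokens append in loop order (closes ascend by construction), and
each opening token is restricted to the slot interval carved out by the
relations to already-placed loops.  Depth-first search over those slots,
smallest first, is deterministic and complete, so unrealizable matrices
fail loudly (`UnrealizableMatrixError`); a node budget guards against
pathological blowup and raises a distinct error if hit.  Final coordinates
place tokens one vertex apart with an extra gap inside arcs whose
endpoints ended up adjacent, keeping outputs Bpseq-valid.

## Numerical and I/O choices

- Coordinates are 1-based closed intervals, matching Bpseq.
- Bpseq parsing is strict: positions must be exactly `1..ℓ` ascending;
  non-reciprocal, self-, and neighbour-pairings, duplicate/missing
  positions, and non-integer fields each raise a distinct named error.
  Blank and `#` lines are skipped; anything else malformed is fatal.
  Bases outside A/C/G/U are tolerated with a logged warning, since real
  database files carry IUPAC ambiguity codes.
- Matrix TSV serialization (`N n` header + `s t c` lines, ascending) is
  canonical and validated on read (entry count, triangle bounds,
  duplicates, symbol alphabet); matrix equality is exact symbol equality
  on the triangle — no wildcard symbol exists in the formalism.
- The worked-example duplex ships with its strand break as a named
  constant (`fixtures.INTERACTION_STRAND_BREAK = 9`); the break is always
  an explicit parameter, never inferred from content.
- Degenerate inputs: empty diagrams are legal everywhere (empty loop
  list, `N = 0` matrix); a 0-loop *pattern* is a usage error, as is a
  pattern whose selected abstraction is empty (the shadow of a
  pseudoknot-free structure).

## Problem sizes

Default test and acceptance runs use diagrams up to 60 vertices,
matrices up to N = 40, 1,000 matcher-oracle trials, 10,000
trichotomy samples and 100–200 realization round-trips — sizes chosen so
the whole suite exercises every contract in well under a minute while the
complexity smoke test still spans an 8× range of N.

## Known limitations

- Input formats: Bpseq (and the package's own matrix TSV/JSON) only; no
  dot-bracket or CT readers.
- Matching is exact and windowed; no similarity scoring, no alignment,
  no approximate or sequence-constrained search.
- The relation matrix determines a structure only up to the endpoint
  order realized by `realize_matrix`; coordinates and unpaired runs are
  not recoverable.
- `block_sizes`/`permute_rri_matrix` use one fixed block order; other
  conventions found in the literature require relabelling by the caller.
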