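"""Loop-pair classification, relation-matrix construction, serialization
and the RRI block permutation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relmat import (
    Loop,
    Relation,
    RelationMatrix,
    annotate_rri,
    block_sizes,
    build_relation_matrix,
    classify_relation,
    collapse_stacks,
    core_of,
    deserialize_matrix,
    enumerate_loops,
    is_pseudoknotted,
    matrix_from_json,
    matrix_to_json,
    permute_rri_matrix,
    serialize_matrix,
)
from relmat.abstractions import core_with_provenance
from relmat.errors import LoopPairError, MatrixFormatError

from conftest import random_diagram, random_matrix


class TestClassify:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((2, 6), (4, 11), Relation.CROSS),    # interleaved intervals
            ((2, 6), (8, 13), Relation.CONCAT),   # disjoint, first left
            ((22, 27), (21, 28), Relation.NEST),  # first strictly inside
            ((1, 3), (4, 6), Relation.CONCAT),    # adjacent disjoint arcs
        ],
    )
    def test_worked_pairs(self, a, b, expected):
        assert classify_relation(a, b) is expected

    def test_unordered_pair_rejected(self):
        with pytest.raises(LoopPairError):
            classify_relation((4, 11), (2, 6))

    def test_shared_endpoint_rejected(self):
        with pytest.raises(LoopPairError):
            classify_relation((2, 6), (6, 9))

    def test_trichotomy_on_random_pairs(self):
        """Exactly one of the three interval predicates holds for any valid
        close-ordered loop pair (10,000 samples)."""
        rng = random.Random(42)
        for _ in range(10_000):
            ia, ja, ib, jb = rng.sample(range(1, 200), 4)
            if ia > ja:
                ia, ja = ja, ia
            if ib > jb:
                ib, jb = jb, ib
            if ja > jb:
                (ia, ja), (ib, jb) = (ib, jb), (ia, ja)
            concat = ia < ja < ib < jb
            nest = ib < ia < ja < jb
            cross = ia < ib < ja < jb
            assert concat + nest + cross == 1
            assert classify_relation((ia, ja), (ib, jb)) is {
                (True, False, False): Relation.CONCAT,
                (False, True, False): Relation.NEST,
                (False, False, True): Relation.CROSS,
            }[(concat, nest, cross)]


class TestBuildMatrix:
    def test_nine_loop_example_counts_and_consistent_cells(self, nineloops):
        m = build_relation_matrix(enumerate_loops(nineloops))
        assert m.n == 9
        assert m.n_entries == 36
        assert sum(1 for _ in m.items()) == 36
        # cells where the published table agrees with its own coordinates
        assert m[1, 2] is Relation.CROSS
        for t in range(3, 10):
            assert m[1, t] is Relation.CONCAT
        assert m[4, 7] is Relation.NEST
        assert m[6, 7] is Relation.NEST
        assert m[8, 9] is Relation.NEST
        for s, t in [(5, 8), (5, 9), (6, 8), (6, 9), (2, 6), (2, 8), (2, 9)]:
            assert m[s, t] is Relation.CONCAT

    def test_pseudoknotted_example_cross_entries(self, pk28):
        loops = enumerate_loops(pk28)
        m = build_relation_matrix(loops)
        crosses = {(s, t) for (s, t), rel in m.items() if rel is Relation.CROSS}
        by_index = {l.index: (l.open, l.close) for l in loops}
        named = {frozenset((by_index[s], by_index[t])) for s, t in crosses}
        assert named == {
            frozenset({(13, 23), (18, 27)}),
            frozenset({(12, 24), (18, 27)}),
        }

    def test_demo_pattern_entries(self, demo_pattern):
        assert demo_pattern.n == 3
        assert demo_pattern[1, 2] is Relation.CROSS
        assert demo_pattern[1, 3] is Relation.CROSS
        assert demo_pattern[2, 3] is Relation.NEST

    def test_single_loop_matrix(self):
        m = build_relation_matrix([Loop(2, 6, 1)])
        assert m.n == 1 and m.n_entries == 0

    def test_unsorted_loops_rejected(self):
        with pytest.raises(LoopPairError):
            build_relation_matrix([Loop(4, 11, 1), Loop(2, 6, 2)])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_entry_count_and_crossfree_matrices(self, seed):
        d = random_diagram(seed)
        m = build_relation_matrix(enumerate_loops(d))
        assert m.n_entries == m.n * (m.n - 1) // 2
        has_cross = any(rel is Relation.CROSS for _, rel in m.items())
        assert has_cross == is_pseudoknotted(d)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_core_matrix_is_restriction_of_original(self, seed):
        """Collapsing and renumbering preserve pairwise relations: the core's
        matrix equals the original matrix restricted to the loops the core
        arcs descend from."""
        d = random_diagram(seed)
        core, origin = core_with_provenance(d)
        cm = build_relation_matrix(enumerate_loops(core))
        full = build_relation_matrix(enumerate_loops(d))
        index_of = {(l.open, l.close): l.index for l in enumerate_loops(d)}
        kept = sorted(index_of[origin[a]] for a in core.sorted_arcs)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                assert cm[a + 1, b + 1] == full[kept[a], kept[b]]


class TestSerialization:
    def test_demo_pattern_tsv_text(self, demo_pattern):
        assert serialize_matrix(demo_pattern) == "N 3\n1\t2\tx\n1\t3\tx\n2\t3\tn\n"

    def test_single_loop_tsv(self):
        assert serialize_matrix(RelationMatrix.from_entries(1, {})) == "N 1\n"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 9))
    def test_roundtrip_tsv_and_json(self, seed, n):
        m = random_matrix(random.Random(seed), n)
        assert deserialize_matrix(serialize_matrix(m)) == m
        assert matrix_from_json(matrix_to_json(m)) == m

    @pytest.mark.parametrize(
        "text",
        [
            "N 3\n1\t2\tx\n1\t3\tx\n2\t2\to\n",            # diagonal entry
            "N 3\n1\t2\tx\n1\t3\tx\n2\t3\tq\n",            # unknown symbol
            "N 3\n1\t2\tx\n1\t3\tx\n",                      # wrong count
            "N 3\n1\t2\tx\n1\t2\to\n1\t3\tx\n2\t3\tn\n",   # duplicate
            "1\t2\tx\n",                                    # missing header
        ],
    )
    def test_tampered_files_rejected(self, text):
        with pytest.raises(MatrixFormatError):
            deserialize_matrix(text)


class TestRriPermutation:
    def test_duplex_block_sizes_and_labels(self, duplex19):
        ann = annotate_rri(duplex19, 9)
        m = build_relation_matrix(enumerate_loops(duplex19))
        assert block_sizes(m, ann) == (2, 2, 3)
        p = permute_rri_matrix(m, ann)
        # loop order already groups INTRA1 < INTER < INTRA2 here, so the
        # permutation is the identity and entries are untouched
        assert p.loop_labels == (1, 2, 3, 4, 5, 6, 7)
        assert p == m

    def test_entries_travel_with_their_loops(self):
        # an interleaved annotation genuinely reorders rows
        from relmat import ArcDiagram

        d = ArcDiagram("", 20, {(2, 5), (8, 11), (3, 14), (9, 17)})
        ann = annotate_rri(d, 6)
        m = build_relation_matrix(enumerate_loops(d))
        p = permute_rri_matrix(m, ann)
        labels = p.loop_labels
        assert labels is not None and sorted(labels) == [1, 2, 3, 4]
        pos = {lab: k + 1 for k, lab in enumerate(labels)}
        for (s, t), rel in m.items():
            ps, pt = pos[s], pos[t]
            assert p[min(ps, pt), max(ps, pt)] == rel

    def test_all_intra1_is_identity(self):
        from relmat import ArcDiagram

        d = ArcDiagram("", 10, {(1, 4), (2, 5)})
        ann = annotate_rri(d, 9)
        m = build_relation_matrix(enumerate_loops(d))
        p = permute_rri_matrix(m, ann)
        assert p == m and p.loop_labels == (1, 2)

    def test_permutation_idempotent(self, duplex19):
        ann = annotate_rri(duplex19, 9)
        m = build_relation_matrix(enumerate_loops(duplex19))
        once = permute_rri_matrix(m, ann)
        twice = permute_rri_matrix(once, ann)
        assert once == twice and once.loop_labels == twice.loop_labels
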