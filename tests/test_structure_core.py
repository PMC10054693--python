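"""Dot-bracket parsing, loop decomposition and motif counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnamotifs.errors import (
    EmptyInputError,
    InvalidCharacterError,
    LimitExceededError,
    PseudoknotError,
    UnbalancedBracketsError,
)
from rnamotifs.structure_core import (
    UNPAIRED,
    Bulge,
    Hairpin,
    Multiloop,
    MotifCounts,
    build_tree,
    count_motifs,
    enumerate_structures,
    motif_counts_scan,
    parse_dot_bracket,
    serialize_pair_table,
    validate_pair_table,
)


class TestParseDotBracket:
    def test_simple_hairpin_pairs(self):
        pt = parse_dot_bracket("(((...)))")
        assert [(i, j) for i, j in enumerate(pt) if j > i] == [
            (0, 8), (1, 7), (2, 6)]

    def test_unpaired_only(self):
        assert parse_dot_bracket(".....") == [UNPAIRED] * 5

    @pytest.mark.parametrize("bad", ["(()", "())", ")(", "("])
    def test_unbalanced(self, bad):
        with pytest.raises(UnbalancedBracketsError):
            parse_dot_bracket(bad)

    @pytest.mark.parametrize("bad", ["..x..", "[[...]]", "(( ))"])
    def test_invalid_characters(self, bad):
        with pytest.raises(InvalidCharacterError):
            parse_dot_bracket(bad)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            parse_dot_bracket("")

    def test_round_trip(self, enumeration_to_14):
        for db in enumeration_to_14:
            assert serialize_pair_table(parse_dot_bracket(db)) == db

    def test_crossing_pairs_rejected_by_validation(self):
        # hand-built pseudoknot: (0,2) crossing (1,3)
        pt = [2, 3, 0, 1]
        with pytest.raises(PseudoknotError):
            validate_pair_table(pt)


class TestBuildTree:
    def test_single_hairpin(self):
        tree = build_tree(parse_dot_bracket("(((...)))"))
        assert len(tree.branches) == 1
        helix = tree.branches[0]
        assert helix.bp == 3
        assert isinstance(helix.child, Hairpin)
        assert helix.child.unpaired == 3

    def test_bulged_helix(self):
        tree = build_tree(parse_dot_bracket("(((..(((...))))))"))
        outer = tree.branches[0]
        assert outer.bp == 3
        bulge = outer.child
        assert isinstance(bulge, Bulge)
        assert bulge.side == "5'"
        assert bulge.unpaired == 2
        inner = bulge.child
        assert inner.bp == 3 and isinstance(inner.child, Hairpin)

    def test_two_branch_multiloop(self):
        tree = build_tree(parse_dot_bracket("((..((...))..((...))..))"))
        outer = tree.branches[0]
        assert outer.bp == 2
        ml = outer.child
        assert isinstance(ml, Multiloop)
        assert len(ml.branches) == 2
        for b in ml.branches:
            assert b.bp == 2 and isinstance(b.child, Hairpin)
            assert b.child.unpaired == 3


class TestCountMotifs:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("(((...)))", dict(bonds=3, helices=1, loops=1, bulges=0,
                              junctions=0, internals=0)),
            (".....", dict(bonds=0, helices=0, loops=0, bulges=0,
                           junctions=0, internals=0)),
            ("((..((...))..))", dict(bonds=4, helices=2, loops=1, bulges=0,
                                     junctions=0, internals=1)),
            ("((..((...))..((...))..))", dict(bonds=6, helices=3, loops=2,
                                              bulges=0, junctions=1,
                                              internals=0)),
            ("((...))((...))", dict(bonds=4, helices=2, loops=2, bulges=0,
                                    junctions=0, internals=0)),
        ],
    )
    def test_examples(self, db, expected):
        counts = count_motifs(build_tree(parse_dot_bracket(db)))
        assert counts == MotifCounts(**expected)
        # the no-tree scan agrees
        assert motif_counts_scan(db) == counts

    def test_unpaired_only_counts_zero(self):
        assert count_motifs(build_tree(parse_dot_bracket("...."))) == MotifCounts()

    def test_scan_rejects_empty(self):
        with pytest.raises(EmptyInputError):
            motif_counts_scan("   ")

    def test_internal_as_bulge_switch(self):
        db = "((..((...))..))"
        counts = count_motifs(build_tree(parse_dot_bracket(db)),
                              internal_as_bulge=True)
        assert counts.bulges == 1 and counts.internals == 0
        assert motif_counts_scan(db, internal_as_bulge=True) == counts


class TestTreeProperties:
    def test_tree_identity_and_oracle_agreement(self, enumeration_to_14):
        """Each helix ends in exactly one loop-type face, so #helices ==
        #hairpins + #bulges + #junctions + #internals; and the tree-based
        and scan-based counters agree structure by structure."""
        for db in enumeration_to_14:
            tree_counts = count_motifs(build_tree(parse_dot_bracket(db)))
            assert tree_counts.helices == (
                tree_counts.loops + tree_counts.bulges
                + tree_counts.junctions + tree_counts.internals
            ), db
            assert tree_counts == motif_counts_scan(db), db
            assert tree_counts.bonds == db.count("(")
            # one base pair implies (at least) one hairpin and vice versa
            assert (tree_counts.loops >= 1) == (tree_counts.bonds >= 1)

    def test_concatenation_additivity(self):
        db1, db2 = "(((...)))", "((..((...))..((...))..))"
        combined = count_motifs(build_tree(parse_dot_bracket(db1 + db2)))
        parts = (count_motifs(build_tree(parse_dot_bracket(db1)))
                 + count_motifs(build_tree(parse_dot_bracket(db2))))
        assert combined == parts

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(5, 12), st.integers(5, 12))
    def test_concatenation_additivity_enumerated(self, l1, l2):
        structs1 = list(enumerate_structures(l1))
        structs2 = list(enumerate_structures(l2))
        db1, db2 = structs1[-1], structs2[-1]
        combined = count_motifs(build_tree(parse_dot_bracket(db1 + db2)))
        assert combined == (count_motifs(build_tree(parse_dot_bracket(db1)))
                            + count_motifs(build_tree(parse_dot_bracket(db2))))


class TestEnumeration:
    @pytest.mark.parametrize(
        "L,expected",
        [(3, {"..."}), (4, {"...."}), (5, {".....", "(...)"})],
    )
    def test_small_cases(self, L, expected):
        assert set(enumerate_structures(L, min_hairpin=3)) == expected

    def test_guard(self):
        with pytest.raises(LimitExceededError):
            list(enumerate_structures(17))

    def test_all_enumerated_structures_are_valid(self, enumeration_to_14):
        for db in enumeration_to_14:
            pt = parse_dot_bracket(db)  # would raise if malformed
            # every hairpin has >= 3 unpaired bases
            for i, j in enumerate(pt):
                if j > i and all(pt[k] == UNPAIRED for k in range(i + 1, j)):
                    assert j - i - 1 >= 3

    def test_brute_force_cross_check_at_L8(self):
        """Enumeration agrees with filtering all 3^8 strings."""
        from itertools import product

        def valid(s):
            try:
                pt = parse_dot_bracket(s)
            except Exception:
                return False
            for i, j in enumerate(pt):
                if j > i and all(pt[k] == UNPAIRED for k in range(i + 1, j)):
                    if j - i - 1 < 3:
                        return False
            return True

        brute = {"".join(p) for p in product(".()", repeat=8) if valid("".join(p))}
        assert set(enumerate_structures(8)) == brute
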