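import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omphylo.phylo_core import (
    Alignment,
    Bipartition,
    InvalidMoveError,
    NewickError,
    Tree,
    bipartitions,
    collapse_low_support,
    parse_newick,
    regraft,
    restrict_to,
    same_topology,
    write_newick,
)
from omphylo.synthetic_data import random_tree


class TestNewick:
    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:1);")
        assert t.tip_labels() == {"A", "B"}
        assert all(tip.length == 1.0 for tip in t.tips())

    def test_supports_attach_to_internal_edges(self):
        t = parse_newick("((A,B)95,(C,D)80);", warn_missing_lengths=False)
        supports = sorted(
            n.support for n in t.postorder() if not n.is_tip and n.support is not None
        )
        assert supports == [80.0, 95.0]
        # the support must sit on the edge subtending the right tips
        ab = t.find_edge({"A", "B"})
        assert ab.support == 95.0

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "(A,B,;", "(A:1,A:2);", "(A:-1,B:1);"],
        ids=["unbalanced", "dangling", "duplicate-tip", "negative-length"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad, warn_missing_lengths=False)

    def test_missing_lengths_default_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="lacks branch lengths"):
            t = parse_newick("((A,B),(C,D));")
        assert all(tip.length == 0.0 for tip in t.tips())

    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_random_trees(self, seed):
        labels = [f"t{i}" for i in range(8)]
        t = random_tree(labels, seed=seed)
        text = write_newick(t)
        back = parse_newick(text)
        assert same_topology(t, back)
        assert write_newick(back) == text

    def test_round_trip_preserves_supports_and_lengths(self):
        text = "((A:0.1,B:0.2)95:0.05,C:0.3,(D:0.4,E:0.5)67:0.06);"
        t = parse_newick(text)
        assert write_newick(t) == text


class TestBipartitions:
    def test_balanced_quartet_single_split(self):
        t = parse_newick("((A,B),(C,D));", warn_missing_lengths=False)
        (bp,) = bipartitions(t)
        assert bp == Bipartition("ABCD", {"C", "D"})

    def test_caterpillar_count_is_n_minus_3(self):
        t = parse_newick("(A,(B,(C,(D,E))));", warn_missing_lengths=False)
        assert len(bipartitions(t)) == 2

    def test_fewer_than_four_tips_yield_empty_set(self):
        t = parse_newick("(A:1,(B:1,C:1):1);")
        assert bipartitions(t) == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_removal_oracle(self, seed):
        labels = [f"t{i}" for i in range(8)]
        t = random_tree(labels, seed=seed)
        # oracle: for every internal edge, the split is (tips below, rest)
        taxa = t.tip_labels()
        expected = set()
        for node in t.postorder():
            if node is t.root:
                continue
            below = node.tip_set()
            if 2 <= len(below) <= len(taxa) - 2:
                expected.add(Bipartition(taxa, below))
        assert bipartitions(t) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_rerooting(self, seed):
        labels = [f"t{i}" for i in range(7)]
        t = random_tree(labels, seed=seed)
        ref = bipartitions(t)
        for lab in labels:
            assert bipartitions(t.rooted_at_edge({lab})) == ref

    def test_normalization_is_idempotent_and_rotation_free(self):
        a = Bipartition("ABCDEF", {"E", "F"})
        b = Bipartition("ABCDEF", {"A", "B", "C", "D"})
        assert a == b and hash(a) == hash(b)
        assert Bipartition(a.taxa, a.side) == a

    def test_conflict_detection(self):
        taxa = "ABCD"
        ab = Bipartition(taxa, {"A", "B"})
        ac = Bipartition(taxa, {"A", "C"})
        assert ab.conflicts_with(ac)
        assert not ab.conflicts_with(ab)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        side=st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=7),
        sub=st.sets(st.sampled_from("ABCDEFGH"), min_size=0, max_size=8),
    )
    def test_complement_symmetry_and_restriction(self, side, sub):
        taxa = set("ABCDEFGH")
        if side == taxa:
            side = side - {"A"}
        bp = Bipartition(taxa, side)
        assert bp == Bipartition(taxa, taxa - side)
        restricted = bp.restrict(sub)
        if restricted is None:
            # the split degenerates: one side vanishes on the subset
            assert not (side & sub) or not ((taxa - side) & sub)
        else:
            assert restricted.taxa == frozenset(sub)
            assert restricted == Bipartition(sub, side & sub)


class TestRegraft:
    def test_identity_move(self, fixture_tree):
        t = regraft(
            fixture_tree,
            {"Negativicutes"},
            {"Peptococcaceae"},
        )
        assert same_topology(t, fixture_tree)

    def test_negativicutes_one_node_rootward(self, fixture_tree):
        t = regraft(
            fixture_tree,
            {"Negativicutes"},
            {"Clostridia_B", "Peptococcaceae"},
        )
        # Negativicutes becomes sister to (Clostridia_B, Peptococcaceae)
        assert t.find_edge({"Clostridia_B", "Peptococcaceae", "Negativicutes"})
        assert same_topology(t, t)  # still a valid binary tree
        assert t.tip_labels() == fixture_tree.tip_labels()

    def test_non_monophyletic_clade_rejected(self, fixture_tree):
        with pytest.raises(InvalidMoveError):
            regraft(fixture_tree, {"Bacilli", "Negativicutes"}, {"Outgroup"})

    def test_target_inside_clade_rejected(self, fixture_tree):
        with pytest.raises(InvalidMoveError):
            regraft(
                fixture_tree,
                {"Peptococcaceae", "Negativicutes"},
                {"Negativicutes"},
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_every_legal_move_keeps_tree_binary(self, seed):
        labels = [f"t{i}" for i in range(7)]
        t = random_tree(labels, seed=seed).unrooted()
        clade = t.find_edge({"t0"}).tip_set()
        edges = [
            n.tip_set()
            for n in t.postorder()
            if n is not t.root and not (n.tip_set() & clade)
        ]
        for target in edges:
            moved = regraft(t, clade, target)
            assert moved.tip_labels() == t.tip_labels()
            assert len(bipartitions(moved)) == len(labels) - 3

    @pytest.mark.parametrize("seed", range(3))
    def test_regraft_back_restores_topology(self, seed):
        labels = [f"t{i}" for i in range(7)]
        t = random_tree(labels, seed=seed).unrooted()
        original_sister = None
        clade = {"t0"}
        node = t.find_edge(clade)
        siblings = [c for c in node.parent.children if c is not node]
        if node.parent.parent is None and len(siblings) != 1:
            original_sister = siblings[0].tip_set()
        else:
            original_sister = siblings[0].tip_set()
        far = [
            n.tip_set()
            for n in t.postorder()
            if n is not t.root
            and not (n.tip_set() & clade)
            and n.tip_set() != original_sister
        ]
        moved = regraft(t, clade, far[0])
        back = regraft(moved, clade, original_sister)
        assert bipartitions(back) == bipartitions(t)


class TestTreeUtilities:
    def test_restrict_to_subset(self, fixture_tree):
        small = restrict_to(
            fixture_tree, {"Outgroup", "Bacilli", "Peptococcaceae", "Negativicutes"}
        )
        assert small.tip_labels() == {
            "Outgroup",
            "Bacilli",
            "Peptococcaceae",
            "Negativicutes",
        }
        (bp,) = bipartitions(small)
        assert bp == Bipartition(small.tip_labels(), {"Peptococcaceae", "Negativicutes"})

    def test_collapse_low_support(self):
        t = parse_newick("(((A:1,B:1)50:1,C:1)90:1,(D:1,E:1)30:1,F:1);")
        collapsed = collapse_low_support(t, 70)
        remaining = {
            n.support for n in collapsed.postorder() if not n.is_tip and n.support
        }
        assert remaining == {90.0}
        assert len(bipartitions(collapsed)) == 1


class TestAlignment:
    def test_round_trip_fasta_and_phylip(self, tmp_path):
        aln = Alignment.from_dict(
            {"taxA": "ACDEF-XKLM", "taxB": "ACDEFGHKLM", "taxC": "MW-YVACDEX"}
        )
        for fmt, name in (("fasta", "a.fasta"), ("phylip", "a.phy")):
            path = tmp_path / name
            aln.write(path, fmt=fmt)
            back = Alignment.read(path, fmt=fmt)
            assert back == aln

    def test_rejects_ragged_and_illegal_input(self):
        with pytest.raises(ValueError, match="unequal"):
            Alignment.from_dict({"A": "ACD", "B": "AC"})
        with pytest.raises(ValueError, match="illegal residue"):
            Alignment.from_dict({"A": "AZ"})
        with pytest.raises(ValueError, match="duplicate"):
            Alignment(["A", "A"], np.zeros((2, 3), dtype=np.uint8))
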