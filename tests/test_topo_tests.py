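import numpy as np
import pytest

from omphylo.phylo_core import (
    Bipartition,
    InvalidMoveError,
    Tree,
    bipartitions,
    parse_newick,
    write_newick,
)
from omphylo.synthetic_data import firmicutes_fixture, perturb_gene_trees
from omphylo.topo_tests import (
    DEFAULT_SCALES,
    BPTable,
    au_pvalues,
    generate_alternative_topologies,
    internode_certainty,
    rell_bootstrap,
)


def caterpillar(n):
    inner = "t1"
    for i in range(2, n + 1):
        inner = f"({inner},t{i})"
    return parse_newick(inner + ";", warn_missing_lengths=False)


class TestAlternativeTopologies:
    def test_fixture_negativicutes_slide(self, fixture_tree):
        alts = generate_alternative_topologies(
            fixture_tree, {"Negativicutes"}, 2, {"Halanaerobiales"}, "N"
        )
        assert [label for label, _ in alts] == ["N1", "N2"]
        n1, n2 = (t for _, t in alts)
        # N1: sister to (Clostridia_B, Peptococcaceae)
        assert n1.find_edge({"Clostridia_B", "Peptococcaceae", "Negativicutes"})
        assert n1.find_edge({"Clostridia_B", "Peptococcaceae"})
        # N2: sister to (Clostridia_A, (Clostridia_B, Peptococcaceae))
        assert n2.find_edge(
            {"Clostridia_A", "Clostridia_B", "Peptococcaceae", "Negativicutes"}
        )
        assert n2.find_edge({"Clostridia_A", "Clostridia_B", "Peptococcaceae"})

    def test_zero_positions_empty_list(self, fixture_tree):
        assert generate_alternative_topologies(
            fixture_tree, {"Negativicutes"}, 0, {"Halanaerobiales"}
        ) == []

    def test_twelve_distinct_alternatives_on_deep_tree(self):
        tree = caterpillar(16)
        alts = generate_alternative_topologies(
            tree, {"t1"}, 6, {"t16"}, "A"
        ) + generate_alternative_topologies(tree, {"t16"}, 6, {"t1"}, "B")
        assert len(alts) == 12
        keys = [bipartitions(t) for _, t in alts]
        ref = bipartitions(tree)
        assert all(k != ref for k in keys)
        assert len({frozenset(k) for k in keys}) == 12

    def test_insufficient_path_is_an_error(self, fixture_tree):
        with pytest.raises(InvalidMoveError, match="5 candidate positions"):
            generate_alternative_topologies(
                fixture_tree, {"Negativicutes"}, 6, {"Halanaerobiales"}
            )

    def test_last_position_clusters_the_two_clades(self, fixture_tree):
        alts = generate_alternative_topologies(
            fixture_tree, {"Negativicutes"}, 5, {"Halanaerobiales"}, "N"
        )
        label, n5 = alts[-1]
        assert label == "N5"
        assert n5.find_edge({"Halanaerobiales", "Negativicutes"})


class TestRellBootstrap:
    def test_dominant_topology_wins_every_scale(self):
        rng = np.random.default_rng(0)
        base = rng.normal(-3, 1, size=200)
        sitell = np.vstack([base, base - 0.2])  # A beats B at every site
        bpt = rell_bootstrap(sitell, DEFAULT_SCALES, 500, seed=1)
        assert np.allclose(bpt.bp[:, 0], 1.0)
        assert np.allclose(bpt.bp[:, 1], 0.0)

    def test_identical_rows_split_ties_evenly(self):
        row = np.random.default_rng(1).normal(-2, 1, size=100)
        bpt = rell_bootstrap(np.vstack([row, row]), [0.5, 1.0], 400, seed=2)
        assert np.allclose(bpt.bp, 0.5)

    def test_rows_sum_to_one_per_scale(self):
        rng = np.random.default_rng(3)
        sitell = rng.normal(-3, 1, size=(4, 150))
        bpt = rell_bootstrap(sitell, DEFAULT_SCALES, 300, seed=3)
        assert np.allclose(bpt.bp.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_independent_monte_carlo_oracle(self):
        # three topologies with known mean gaps; compare BP at r = 1 with a
        # naive per-replicate resampler
        rng = np.random.default_rng(4)
        n = 300
        sitell = np.vstack(
            [
                rng.normal(-3.000, 1.0, size=n),
                rng.normal(-3.003, 1.0, size=n),
                rng.normal(-3.010, 1.0, size=n),
            ]
        )
        n_boot = 4000
        bpt = rell_bootstrap(sitell, [1.0], n_boot, seed=5)
        oracle_rng = np.random.default_rng(99)
        wins = np.zeros(3)
        for _ in range(n_boot):
            idx = oracle_rng.integers(0, n, size=n)
            totals = sitell[:, idx].sum(axis=1)
            wins[np.argmax(totals)] += 1
        oracle_bp = wins / n_boot
        # both estimates carry binomial noise: compare with a two-sample
        # 3-sigma bound
        sigma = np.sqrt(2 * oracle_bp * (1 - oracle_bp) / n_boot)
        assert (np.abs(bpt.bp[0] - oracle_bp) <= 3 * sigma + 2 / n_boot).all()

    def test_few_replicates_warn(self):
        sitell = np.zeros((2, 50))
        with pytest.warns(UserWarning, match="unstable"):
            rell_bootstrap(sitell, [1.0], 50, seed=1)


class TestAUPValues:
    @staticmethod
    def table(bp_column, scales=DEFAULT_SCALES, n_boot=10_000):
        scales = np.asarray(scales, dtype=float)
        bp = np.column_stack([bp_column, 1.0 - np.asarray(bp_column)])
        return BPTable(["A", "B"], scales, bp, n_boot)

    def test_constant_half_gives_p_half(self):
        res = au_pvalues(self.table(np.full(len(DEFAULT_SCALES), 0.5)))
        assert res["A"].p_au == pytest.approx(0.5, abs=1e-9)
        assert res["A"].d == pytest.approx(0.0, abs=1e-9)
        assert res["A"].c == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_always_best_is_one(self):
        res = au_pvalues(self.table(np.ones(len(DEFAULT_SCALES))))
        assert res["A"].p_au == 1.0
        assert res["B"].p_au == 0.0

    def test_location_shift_does_not_decrease_p(self):
        rng = np.random.default_rng(7)
        base = rng.normal(-3, 1, size=(2, 400))
        ps = []
        for delta in (0.0, 0.02, 0.05, 0.1):
            shifted = base.copy()
            shifted[0] += delta
            bpt = rell_bootstrap(shifted, DEFAULT_SCALES, 2000, seed=11)
            ps.append(au_pvalues(bpt)["T0"].p_au)
        assert all(b >= a - 0.02 for a, b in zip(ps, ps[1:]))


class TestInternodeCertainty:
    def test_all_congruent_gene_trees_give_ic_one(self, fixture_tree):
        genes = [fixture_tree.copy() for _ in range(20)]
        ann = internode_certainty(fixture_tree, genes)
        values = [rec.ic for rec in ann.records.values()]
        assert values and all(v == 1.0 for v in values)

    @pytest.mark.parametrize(
        "n_support,n_conflict,expected",
        [(50, 50, 0.0), (75, 25, 0.18872187554086717)],
    )
    def test_two_way_conflict_closed_forms(self, n_support, n_conflict, expected):
        ref = parse_newick("((A,B),(C,D),E);", warn_missing_lengths=False)
        conflict = parse_newick("((A,C),(B,D),E);", warn_missing_lengths=False)
        genes = [ref.copy()] * n_support + [conflict.copy()] * n_conflict
        ann = internode_certainty(ref, genes)
        bp = Bipartition("ABCDE", {"A", "B"})
        assert ann.value(bp) == pytest.approx(expected, abs=1e-6)

    def test_dominant_conflict_gets_negative_sign(self):
        ref = parse_newick("((A,B),(C,D),E);", warn_missing_lengths=False)
        conflict = parse_newick("((A,C),(B,D),E);", warn_missing_lengths=False)
        genes = [ref.copy()] * 25 + [conflict.copy()] * 75
        bp = Bipartition("ABCDE", {"A", "B"})
        assert internode_certainty(ref, genes).value(bp) == pytest.approx(
            -0.18872187554086717, abs=1e-6
        )

    def test_low_support_edges_are_collapsed_first(self):
        ref = parse_newick("((A,B),(C,D),E);", warn_missing_lengths=False)
        weak = parse_newick("((A:1,C:1)40:1,(B:1,D:1)95:1,E:1);")
        genes = [weak] * 10
        bp = Bipartition("ABCDE", {"A", "B"})
        ann = internode_certainty(ref, genes, support_threshold=70)
        # the 40%-supported AC|BDE edge collapses, but BD|ACE survives and
        # still conflicts with AB|CDE
        assert ann.records[bp].conflict == 10
        assert ann.value(bp) == -1.0

    def test_uninformative_internode_reported_missing(self, fixture_tree):
        # gene trees sampling only the deep lineages say nothing about the
        # clostridial internodes
        from omphylo.phylo_core import restrict_to

        keep = {"Outgroup", "Halanaerobiales", "Natranaerobiales", "Bacilli"}
        genes = [restrict_to(fixture_tree, keep) for _ in range(6)]
        ann = internode_certainty(fixture_tree, genes)
        assert any(rec.ic is None for rec in ann.records.values())
        assert any(rec.ic is not None for rec in ann.records.values())

    def test_invariant_under_order_and_rerooting(self, fixture_tree):
        genes = perturb_gene_trees(fixture_tree, 12, 1, 0.0, seed=5)
        ann1 = internode_certainty(fixture_tree, genes)
        ann2 = internode_certainty(fixture_tree, list(reversed(genes)))
        rerooted = [g.rooted_at_edge({sorted(g.tip_labels())[0]}) for g in genes]
        ann3 = internode_certainty(fixture_tree, rerooted)
        for bp, rec in ann1.records.items():
            assert ann2.records[bp].ic == rec.ic
            assert ann3.records[bp].ic == rec.ic

    def test_annotation_written_onto_tree(self, fixture_tree):
        genes = [fixture_tree.copy() for _ in range(5)]
        ann = internode_certainty(fixture_tree, genes)
        tree = ann.annotate(fixture_tree)
        sups = [
            n.support
            for n in tree.postorder()
            if not n.is_tip and n.support is not None
        ]
        assert sups and all(s == 1.0 for s in sups)
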