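"""Node categorization: connectivity x scope partitions across groups."""

import pytest

from helpers import make_cohort
from mtcooc.categorize import categorize_nodes, local_pair_fraction, neighbors_of
from mtcooc.cooccurrence import build_all_masters, build_master_network
from mtcooc.synthetic import toy_annotation


def two_group_cohort():
    """Group 1: sites 1,2 (perfect pair) and 3; group 2: sites 3 and 4."""
    rows_g1 = ["GGAA", "GGAA", "AATA", "AAAA"]
    rows_g2 = ["AATT", "AATT", "AAAA", "AAAA"]
    return make_cohort(rows_g1 + rows_g2, groups=[1] * 4 + [2] * 4)


class TestCatalog:
    def test_scope_assignment(self):
        masters = build_all_masters(two_group_cohort())
        catalog = categorize_nodes(masters)
        assert catalog.scope[1] == "local"  # variable only in group 1
        assert catalog.scope[4] == "local"  # variable only in group 2
        assert catalog.scope[3] == "global"  # variable in both groups

    def test_connectivity_assignment(self):
        masters = build_all_masters(two_group_cohort())
        catalog = categorize_nodes(masters)
        assert catalog.connectivity[1][1] == "connected"
        assert catalog.connectivity[1][3] == "isolated"
        assert catalog.connectivity[2][3] == "connected"

    def test_partitions_are_exact(self):
        masters = build_all_masters(two_group_cohort())
        catalog = categorize_nodes(masters)
        for g in catalog.groups:
            everything = catalog.nodes(g)
            conn = catalog.nodes(g, connectivity="connected")
            isol = catalog.nodes(g, connectivity="isolated")
            assert conn | isol == everything and not conn & isol
            by_scope = [catalog.nodes(g, scope=s) for s in ("local", "mixed", "global")]
            assert set.union(*by_scope) == everything
            assert sum(len(s) for s in by_scope) == len(everything)

    def test_synthetic_partition_conservation(self, default_run, default_annotation):
        cohort, _ = default_run
        masters = build_all_masters(cohort, annotation=default_annotation)
        catalog = categorize_nodes(masters)
        for g in catalog.groups:
            n = len(catalog.nodes(g))
            parts = sum(len(catalog.nodes(g, scope=s)) for s in ("local", "mixed", "global"))
            assert parts == n

    def test_global_connected_intersection(self, default_run, default_annotation):
        cohort, manifest = default_run
        masters = build_all_masters(cohort, annotation=default_annotation)
        catalog = categorize_nodes(masters)
        expected = {
            p
            for t in manifest.pairs
            if t.scope == "global"
            for p in (t.position_i, t.position_j)
        }
        assert catalog.global_connected() == expected

    def test_single_group_warns_and_skips_scope(self):
        _, master = build_master_network(make_cohort(["GG", "GG", "AA", "AA"]), 1)
        with pytest.warns(UserWarning, match="two groups"):
            catalog = categorize_nodes({1: master})
        assert catalog.scope == {}
        assert catalog.nodes(1, connectivity="connected")

    def test_dropping_a_group_only_narrows_scope(self, default_run, default_annotation):
        """Removing a group can move nodes global->mixed or mixed->local, never up."""
        cohort, _ = default_run
        masters = build_all_masters(cohort, annotation=default_annotation)
        full = categorize_nodes(masters)
        reduced = categorize_nodes({g: m for g, m in masters.items() if g != 8})
        rank = {"local": 0, "mixed": 1, "global": 2}
        for p, scope in reduced.scope.items():
            assert rank[scope] <= rank[full.scope[p]]


class TestLocalPairFraction:
    def test_all_local_and_no_local_edges(self):
        masters = build_all_masters(two_group_cohort())
        catalog = categorize_nodes(masters)
        # group 1's only edge (1,2) is local-local -> 100%
        assert local_pair_fraction(catalog, masters[1]) == pytest.approx(100.0)
        # group 2's edge (3,4) mixes global and local -> 0%
        assert local_pair_fraction(catalog, masters[2]) == pytest.approx(0.0)

    def test_edgeless_master_is_undefined(self):
        cohort = make_cohort(["GA", "AA", "AG", "AA"], groups=[1, 1, 2, 2])
        masters = build_all_masters(cohort)
        catalog = categorize_nodes(masters)
        assert local_pair_fraction(catalog, masters[1]) is None

    def test_planted_scope_fraction(self, default_run, default_annotation):
        cohort, manifest = default_run
        masters = build_all_masters(cohort, annotation=default_annotation)
        catalog = categorize_nodes(masters)
        for g in catalog.groups:
            planted = manifest.in_scope_pairs(g)
            n_local = sum(
                1 for (i, j) in planted if manifest.scope_of_pair(i, j) == "local"
            )
            assert local_pair_fraction(catalog, masters[g]) == pytest.approx(
                100.0 * n_local / len(planted)
            )


class TestNeighbors:
    def test_isolated_node_has_no_neighbors(self):
        _, master = build_master_network(make_cohort(["GA", "AA", "AA"]), 1)
        assert neighbors_of(master, 1) == []

    def test_star_hub_lists_all_leaves(self):
        # hub minor carried by {0,1,2}; leaves by singletons {0}, {1}, {2}:
        # C(hub, leaf) = 1/3, C(leaf, leaf) = 0 -> star at C_th = 1/3
        rows = ["GGAA", "GAGA", "GAAG", "AAAA", "AAAA", "AAAA", "AAAA"]
        _, master = build_master_network(make_cohort(rows), 1, c_th=1 / 3)
        ann = toy_annotation(2000)
        result = neighbors_of(master, 1, ann)
        assert [p for p, _ in result] == [2, 3, 4]
        assert all(feats == ann.features_at(p) for p, feats in result)

    def test_unknown_position_raises(self):
        _, master = build_master_network(make_cohort(["GA", "AA"]), 1)
        with pytest.raises(KeyError):
            neighbors_of(master, 999)
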