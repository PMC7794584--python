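"""Co-occurrence frequency, per-sample motifs, master networks, and the
brute-force oracle equivalence on small random alignments."""

import numpy as np
import pytest

from helpers import brute_master_edges, make_cohort, random_matrix
from mtcooc.cooccurrence import (
    GroupContext,
    average_degree,
    build_master_network,
    build_sample_motifs,
    cooccurrence_frequency,
    merge_master,
)
from mtcooc.errors import UndefinedAlleleError
from mtcooc.nulls import sample_null_network


class TestFrequency:
    def test_perfect_cooccurrence_is_one(self):
        m = np.array([list("GT")] * 5 + [list("AC")] * 5, dtype="<U1")
        assert cooccurrence_frequency(m, 0, 1, "G", "T") == 1.0

    def test_never_joint_is_zero(self):
        m = np.array([list("GC"), list("AT"), list("AC")], dtype="<U1")
        assert cooccurrence_frequency(m, 0, 1, "G", "T") == 0.0

    def test_partial_overlap_hand_value(self):
        # x at i in 4 of 6 samples, y at j in 2, jointly in 2 -> 2^2/(4*2) = 0.5
        rows = ["GT", "GT", "GA", "GA", "AA", "AA"]
        m = np.array([list(r) for r in rows], dtype="<U1")
        assert cooccurrence_frequency(m, 0, 1, "G", "T") == pytest.approx(0.5)

    def test_symmetric_under_argument_swap(self):
        rows = ["GT", "GA", "AT", "AA", "GT"]
        m = np.array([list(r) for r in rows], dtype="<U1")
        assert cooccurrence_frequency(m, 0, 1, "G", "T") == pytest.approx(
            cooccurrence_frequency(m[:, ::-1], 0, 1, "T", "G")
        )

    def test_missing_data_excluded_from_all_counts(self):
        # the N-carrying sample drops out of N(x), N(y) and N(xy):
        # remaining counts N(G)=1, N(T)=2, N(GT)=1 -> C = 0.5
        # (counting the N sample as a mismatch would give 1/(2*2) = 0.25)
        rows = ["GT", "GN", "AT"]
        m = np.array([list(r) for r in rows], dtype="<U1")
        assert cooccurrence_frequency(m, 0, 1, "G", "T") == pytest.approx(0.5)

    def test_absent_allele_raises(self):
        m = np.array([list("AT"), list("AC")], dtype="<U1")
        with pytest.raises(UndefinedAlleleError):
            cooccurrence_frequency(m, 0, 1, "G", "T")


class TestMotifsAndMaster:
    def test_three_perfect_minors_form_a_triangle(self):
        # two carriers share minor alleles at three sites -> complete K3
        rows = ["GGG", "GGG", "AAA", "AAA", "AAA"]
        ctx = GroupContext(make_cohort(rows), 1)
        motifs = build_sample_motifs(ctx, 0, c_th=1.0)
        assert len(motifs.edges) == 3
        assert motifs.nodes == {1, 2, 3}

    def test_threshold_excludes_imperfect_pairs(self):
        rows = ["GT", "GA", "AA", "AA", "AA"]  # C = 1/(2*1) = 0.5 for s0's pair
        ctx = GroupContext(make_cohort(rows), 1)
        assert build_sample_motifs(ctx, 0, c_th=1.0).edges == set()
        assert len(build_sample_motifs(ctx, 0, c_th=0.5).edges) == 1

    def test_sample_without_minor_alleles_is_empty(self):
        rows = ["GT", "GT", "AA", "AA", "AA"]
        ctx = GroupContext(make_cohort(rows), 1)
        assert build_sample_motifs(ctx, 4, c_th=1.0).nodes == set()

    def test_merge_deduplicates_shared_edges(self):
        rows = ["GG", "GG", "AA", "AA"]  # two carriers share one perfect edge
        ctx = GroupContext(make_cohort(rows), 1)
        motifs = [build_sample_motifs(ctx, k, 1.0) for k in range(4)]
        master = merge_master(motifs, ctx, 1.0)
        assert master.n_edges == 1
        assert len(master.edges) == 1
        (edge,) = master.edges.values()
        assert set(edge.support) == {"s0", "s1"}

    def test_disjoint_sample_edges_sum(self):
        # carriers {s0} and {s1} contribute one disjoint perfect edge each
        rows = ["GGAA", "AAGG", "AAAA", "AAAA"]
        _, master = build_master_network(make_cohort(rows), 1, c_th=1.0)
        assert master.position_pairs == {(1, 2), (3, 4)}

    def test_master_includes_isolated_nodes(self):
        rows = ["GGT", "AAT", "AAA"]  # site 3's carriers {0,1} differ from {0}
        _, master = build_master_network(make_cohort(rows), 1, c_th=1.0)
        assert master.nodes == {1, 2, 3}
        assert master.isolated_nodes() == {3}

    def test_perfect_edge_iff_carrier_sets_equal(self, rng):
        """At C_th = 1 an edge exists exactly when the two minor-allele
        carrier sets coincide — an independent set-equality check."""
        for _ in range(25):
            matrix = random_matrix(rng, 12, 6)
            cohort = make_cohort(["".join(r) for r in matrix])
            ctx, master = build_master_network(cohort, 1, c_th=1.0)
            for i in ctx.positions:
                for j in ctx.positions:
                    if i >= j:
                        continue
                    expected = False
                    for x in ctx.site_of[i].minor_alleles:
                        for y in ctx.site_of[j].minor_alleles:
                            col_i, col_j = ctx.col_of[i], ctx.col_of[j]
                            ok = np.isin(matrix[:, col_i], list("ACGT")) & np.isin(
                                matrix[:, col_j], list("ACGT")
                            )
                            set_x = {k for k in np.nonzero(ok)[0] if matrix[k, col_i] == x}
                            set_y = {k for k in np.nonzero(ok)[0] if matrix[k, col_j] == y}
                            if set_x and set_x == set_y:
                                expected = True
                    assert ((i, j) in master.position_pairs) == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_raising_threshold_never_adds_edges(self, seed):
        rng = np.random.default_rng(seed)
        cohort = make_cohort(["".join(r) for r in random_matrix(rng, 10, 8)])
        _, loose = build_master_network(cohort, 1, c_th=0.4)
        _, strict = build_master_network(cohort, 1, c_th=0.9)
        assert set(strict.edges) <= set(loose.edges)

    def test_sample_order_permutation_invariance(self, rng):
        rows = ["".join(r) for r in random_matrix(rng, 10, 8)]
        _, a = build_master_network(make_cohort(rows), 1, c_th=1.0)
        _, b = build_master_network(make_cohort(rows[::-1]), 1, c_th=1.0)
        assert set(a.edges) == set(b.edges)
        assert a.nodes == b.nodes

    @pytest.mark.parametrize("seed, c_th", [(s, t) for s in range(6) for t in (1.0, 0.6)])
    def test_matches_bruteforce_enumeration(self, seed, c_th):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, 15, 10)
        cohort = make_cohort(["".join(r) for r in matrix])
        _, master = build_master_network(cohort, 1, c_th=c_th)
        assert set(master.edges) == brute_master_edges(matrix, c_th)


class TestAverageDegree:
    def test_triangle(self):
        rows = ["GGG", "GGG", "AAA", "AAA"]
        _, master = build_master_network(make_cohort(rows), 1)
        assert average_degree(master) == pytest.approx(2.0)

    def test_path_plus_isolated_node(self):
        # carrier sets {0,1}, {0,1,2}, {1,2}, {3} give a 3-node path plus one
        # isolated variable site at C_th = 0.5: <k> = 2*2/4 = 1
        rows = ["GGAA", "GGGA", "AGGA", "AAAG", "AAAA", "AAAA", "AAAA"]
        _, master = build_master_network(make_cohort(rows), 1, c_th=0.5)
        assert master.position_pairs == {(1, 2), (2, 3)}
        assert len(master.nodes) == 4
        assert average_degree(master, "all") == pytest.approx(1.0)
        assert average_degree(master, "connected") == pytest.approx(4 / 3)

    def test_empty_node_set_raises(self):
        rows = ["AAAA", "AAAA"]
        _, master = build_master_network(make_cohort(rows), 1)
        with pytest.raises(ValueError):
            average_degree(master)

    def test_random_graph_mean_degree_matches_closed_form(self, rng):
        """Monte Carlo <k> of G(N, p) stays within 3 SE of p (N - 1)."""
        n, nc, reps = 30, 60, 400
        p = 2 * nc / (n * (n - 1))
        degrees = [
            2 * sample_null_network(n, nc, rng).number_of_edges() / n
            for _ in range(reps)
        ]
        expected = p * (n - 1)
        m = n * (n - 1) / 2
        se_edges = np.sqrt(m * p * (1 - p) / reps)
        se_degree = 2 * se_edges / n
        assert abs(np.mean(degrees) - expected) < 3 * se_degree
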