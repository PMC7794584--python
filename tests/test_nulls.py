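"""Random-network nulls: connectance matching, ensemble statistics, flagging."""

import numpy as np
import pandas as pd
import pytest

from helpers import make_cohort
from mtcooc.genenet import GeneNetwork, build_gene_network
from mtcooc.cooccurrence import build_master_network
from mtcooc.nulls import (
    NullEnsemble,
    connection_probability,
    deviating_gene_pairs,
    null_gene_ensemble,
    sample_null_network,
)
from mtcooc.synthetic import toy_annotation


class TestConnectionProbability:
    def test_direct_evaluation(self):
        assert connection_probability(4, 3) == pytest.approx(6 / 12)

    def test_zero_links_gives_zero(self):
        assert connection_probability(10, 0) == 0.0

    def test_excess_links_rejected(self):
        with pytest.raises(ValueError):
            connection_probability(4, 7)


class TestSampler:
    def test_zero_links_always_empty(self, rng):
        g = sample_null_network(12, 0, rng)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 12

    def test_node_labels_reused(self, rng):
        labels = [101, 205, 333]
        g = sample_null_network(labels, 2, rng)
        assert set(g.nodes) == set(labels)

    def test_mean_edge_count_matches_binomial(self, rng):
        n, nc, reps = 40, 80, 500
        p = connection_probability(n, nc)
        m = n * (n - 1) / 2
        counts = [sample_null_network(n, nc, rng).number_of_edges() for _ in range(reps)]
        se = np.sqrt(m * p * (1 - p) / reps)
        assert abs(np.mean(counts) - p * m) < 3 * se

    def test_seed_reproducibility(self):
        a = sample_null_network(20, 30, seed=5)
        b = sample_null_network(20, 30, seed=5)
        assert set(a.edges) == set(b.edges)


@pytest.fixture(scope="module")
def tiny_cohort():
    # group 1: perfect pair (1,2) carried by {s0,s1}; singleton at 3
    rows = ["GGAA", "GGAA", "AATA", "AAAA", "AAAA"]
    return make_cohort(rows)


class TestEnsemble:
    def test_bit_reproducible(self, tiny_cohort):
        ann = toy_annotation(2000)
        a = null_gene_ensemble(tiny_cohort, 1, ann, n_replicates=20, seed=3)
        b = null_gene_ensemble(tiny_cohort, 1, ann, n_replicates=20, seed=3)
        assert a.mean == b.mean and a.sd == b.sd
        pd.testing.assert_frame_equal(a.replicate_summaries, b.replicate_summaries)

    def test_no_real_links_gives_empty_null(self):
        cohort = make_cohort(["GA", "AT", "AA", "AA"])  # two isolated singletons
        ensemble = null_gene_ensemble(cohort, 1, toy_annotation(2000), 10, seed=1)
        assert ensemble.mean == {} and ensemble.sd == {}

    def test_single_sample_networks_have_matched_density(self, tiny_cohort):
        """Each replicate's total links stay near the real per-sample counts."""
        ann = toy_annotation(2000)
        ensemble = null_gene_ensemble(tiny_cohort, 1, ann, n_replicates=300, seed=9)
        # the real group has 1 link carried by 2 samples; each carrier's
        # 2-node network has p = 1, so the union always has exactly 1 link
        assert (ensemble.replicate_summaries["nc"] == 1).all()

    def test_replicate_count_enforced(self, tiny_cohort):
        with pytest.raises(ValueError):
            null_gene_ensemble(tiny_cohort, 1, toy_annotation(2000), n_replicates=1)


class TestDeviation:
    def ensemble_with(self, mean, sd, pair=("GENE1", "GENE2"), group=1):
        ens = NullEnsemble(group=group, n_replicates=10, seed=0)
        key = tuple(sorted(pair))
        ens.mean[key] = mean
        ens.sd[key] = sd
        return ens

    def real_with(self, weight, pair=("GENE1", "GENE2"), group=1):
        net = GeneNetwork(group=group)
        if weight:
            net.weights[tuple(sorted(pair))] = weight
        return net

    def test_weight_at_mean_not_flagged(self):
        report = deviating_gene_pairs(self.real_with(5), self.ensemble_with(5.0, 1.0))
        assert report.empty

    def test_two_sd_above_flagged(self):
        report = deviating_gene_pairs(self.real_with(7), self.ensemble_with(5.0, 1.0))
        assert report.iloc[0]["direction"] == "above"

    def test_below_band_flagged(self):
        report = deviating_gene_pairs(self.real_with(2), self.ensemble_with(5.0, 1.0))
        assert report.iloc[0]["direction"] == "below"

    def test_unseen_in_null_is_sharp_above(self):
        ens = NullEnsemble(group=1, n_replicates=10, seed=0)
        report = deviating_gene_pairs(self.real_with(1), ens)
        assert report.iloc[0]["direction"] == "above"
        assert report.iloc[0]["null_sd"] == 0.0

    def test_absent_everywhere_never_reported(self):
        report = deviating_gene_pairs(
            self.real_with(0), NullEnsemble(group=1, n_replicates=10, seed=0),
            all_rows=True,
        )
        assert report.empty

    def test_group_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviating_gene_pairs(self.real_with(1, group=2), self.ensemble_with(1, 1))

    def test_flagging_monotone_in_distance(self):
        ens = self.ensemble_with(5.0, 2.0)
        flagged = [
            not deviating_gene_pairs(self.real_with(w), ens).empty
            for w in (5, 6, 7, 8, 9)
        ]
        assert flagged == sorted(flagged)

    def test_planted_heavy_self_pair_flagged_above(self, default_run, default_annotation):
        """The planted density inside gene blocks exceeds the uniform null."""
        cohort, _ = default_run
        ctx, master = build_master_network(cohort, 1, annotation=default_annotation)
        real = build_gene_network(master, default_annotation)
        ensemble = null_gene_ensemble(
            cohort, 1, default_annotation, n_replicates=100, seed=12, ctx=ctx
        )
        report = deviating_gene_pairs(real, ensemble)
        above = report[report["direction"] == "above"]
        # the planted pairs sit within single gene blocks -> heavy self-pairs
        self_pairs = above[above["gene_a"] == above["gene_b"]]
        assert not self_pairs.empty
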