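"""Erdős–Rényi null ensembles matched to the real per-sample motif networks.

For each sample, a random graph G(N, p) is drawn over the sample's own
motif-network node set, with the connection probability matched to the
real network's connectance:

    p = 2 Nc / (N (N - 1))

where N is the sample's node count and Nc its link count. The per-sample
random graphs of a group are merged (union) into a random master network
and pushed through the same gene mapping as the real data; repeating this
gives, per gene pair, a null mean and standard deviation of the weight.
A real gene pair deviates when its weight falls outside mean +/- SD — a
descriptive band, not an inferential test. Gene pairs never seen in any
replicate have mean = SD = 0, so any real occurrence of them is flagged
"above"; this sharp-band consequence is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .alignment import AlignedCohort
from .cooccurrence import GroupContext, build_sample_motifs
from .genenet import GeneNetwork, GenePair, _pair


def connection_probability(n_nodes: int, n_links: int) -> float:
    """Eq.-matched connectance p = 2 Nc / (N (N-1)); 0 for a single node."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    max_links = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_links <= max_links:
        raise ValueError(f"link count {n_links} outside [0, {max_links}] for N={n_nodes}")
    if n_nodes == 1:
        return 0.0
    return 2.0 * n_links / (n_nodes * (n_nodes - 1))


def _random_pairs(
    labels: Sequence[int], p: float, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Each unordered label pair independently present with probability p."""
    pairs = list(combinations(sorted(labels), 2))
    if not pairs or p <= 0.0:
        return set()
    keep = rng.random(len(pairs)) < p
    return {pair for pair, k in zip(pairs, keep) if k}


def sample_null_network(
    nodes: int | Sequence[int],
    n_links: int,
    seed: int | np.random.Generator = 0,
) -> nx.Graph:
    """Draw one G(N, p) random graph with p matched to (N, Nc).

    *nodes* is either a node count (labels ``0..N-1``) or the real
    network's node labels, which the null reuses.
    """
    labels = list(range(nodes)) if isinstance(nodes, int) else list(nodes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = connection_probability(len(labels), n_links)
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from(_random_pairs(labels, p, rng))
    return g


@dataclass
class NullEnsemble:
    """Per-gene-pair weight statistics over replicate random networks."""

    group: int
    n_replicates: int
    seed: int
    mean: dict[GenePair, float] = field(default_factory=dict)
    sd: dict[GenePair, float] = field(default_factory=dict)
    replicate_summaries: pd.DataFrame | None = None  # columns: replicate, nc, mean_degree

    def pairs(self) -> set[GenePair]:
        return set(self.mean)

    def stats(self, gene_a: str, gene_b: str) -> tuple[float, float]:
        key = _pair(gene_a, gene_b)
        return self.mean.get(key, 0.0), self.sd.get(key, 0.0)


def null_gene_ensemble(
    cohort: AlignedCohort,
    group: int,
    annotation: GenomeAnnotation,
    n_replicates: int = 100,
    seed: int = 0,
    c_th: float = 1.0,
    ctx: GroupContext | None = None,
) -> NullEnsemble:
    """Build the null ensemble for one altitude group.

    Deterministic given *seed*: one generator drives every draw in replicate
    order. The population SD (ddof=0) is reported, matching the descriptive
    use of the band.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    ctx = ctx or GroupContext(cohort, group, annotation=annotation)
    motifs = [build_sample_motifs(ctx, k, c_th) for k in range(len(ctx.sample_ids))]
    per_sample: list[tuple[list[int], float]] = []
    for m in motifs:
        labels = sorted(m.nodes)
        n_links = len({(k[0], k[1]) for k in m.edges})
        p = connection_probability(max(len(labels), 1), n_links) if labels else 0.0
        per_sample.append((labels, p))

    features: dict[int, list[str]] = {
        pos: annotation.features_at(pos) for pos in ctx.positions
    }
    n_nodes_group = max(len(ctx.positions), 1)

    rng = np.random.default_rng(seed)
    sums: dict[GenePair, float] = {}
    sumsqs: dict[GenePair, float] = {}
    summaries = []
    for rep in range(n_replicates):
        union: set[tuple[int, int]] = set()
        for labels, p in per_sample:
            if labels:
                union |= _random_pairs(labels, p, rng)
        weights: dict[GenePair, int] = {}
        for (i, j) in union:
            for fa in features[i]:
                for fb in features[j]:
                    key = _pair(fa, fb)
                    weights[key] = weights.get(key, 0) + 1
        for key, w in weights.items():
            sums[key] = sums.get(key, 0.0) + w
            sumsqs[key] = sumsqs.get(key, 0.0) + w * w
        summaries.append(
            {
                "replicate": rep,
                "nc": len(union),
                "mean_degree": 2.0 * len(union) / n_nodes_group,
            }
        )

    ensemble = NullEnsemble(
        group=group,
        n_replicates=n_replicates,
        seed=seed,
        replicate_summaries=pd.DataFrame(summaries),
    )
    for key, total in sums.items():
        mean = total / n_replicates
        var = sumsqs[key] / n_replicates - mean * mean
        ensemble.mean[key] = mean
        ensemble.sd[key] = float(np.sqrt(max(var, 0.0)))
    return ensemble


def deviating_gene_pairs(
    real: GeneNetwork,
    ensemble: NullEnsemble,
    all_rows: bool = False,
) -> pd.DataFrame:
    """Gene pairs whose real weight falls outside the null mean +/- SD band.

    Pairs absent from both the real network and every replicate are never
    reported. ``direction`` is ``"above"`` or ``"below"``; with
    ``all_rows=True`` non-deviating pairs are included with an empty
    direction.
    """
    if real.group != ensemble.group:
        raise ValueError(
            f"real network is group {real.group}, ensemble is group {ensemble.group}"
        )
    considered: Iterable[GenePair] = sorted(set(real.weights) | ensemble.pairs())
    rows = []
    for (a, b) in considered:
        w = real.weight(a, b)
        mean, sd = ensemble.stats(a, b)
        if w > mean + sd:
            direction = "above"
        elif w < mean - sd:
            direction = "below"
        else:
            direction = ""
        if direction or all_rows:
            rows.append(
                {
                    "group": real.group,
                    "gene_a": a,
                    "gene_b": b,
                    "real_weight": w,
                    "null_mean": mean,
                    "null_sd": sd,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "gene_a", "gene_b", "real_weight", "null_mean", "null_sd", "direction",
        ],
    )
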