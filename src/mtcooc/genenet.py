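"""Weighted gene-gene interaction networks from master co-occurrence networks.

Each master-network link (a pair of variable-site positions) is mapped to
the features covering its endpoints; every (feature_i, feature_j)
combination contributes 1 to that unordered gene pair's weight, so a link
whose endpoint sits in overlapping genes (e.g. the ATP8/ATP6 overlap)
counts toward every covering pair, and positions inside no feature map to
"intergenic" rather than being dropped. Self-pairs (both endpoints in the
same gene, e.g. CYB-CYB) are retained. Consequently

    sum of weights == sum over master links of |features_i| * |features_j|

holds exactly — a useful conservation check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .annotation import GenomeAnnotation
from .cooccurrence import MasterNetwork

#: unordered gene pair, stored sorted
GenePair = tuple[str, str]


def _pair(a: str, b: str) -> GenePair:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Weighted graph over genome features for one altitude group."""

    group: int
    weights: dict[GenePair, int] = field(default_factory=dict)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.weights for g in pair}

    def weight(self, gene_a: str, gene_b: str) -> int:
        return self.weights.get(_pair(gene_a, gene_b), 0)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in sorted(self.weights.items()):
            g.add_edge(a, b, weight=w)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "weight": w, "group": self.group}
            for (a, b), w in sorted(self.weights.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "group"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph(), str(path))


def feature_multiplicity_sum(
    pairs: set[tuple[int, int]], annotation: GenomeAnnotation
) -> int:
    """Independent side of the weight-conservation identity."""
    return sum(
        len(annotation.features_at(i)) * len(annotation.features_at(j))
        for (i, j) in pairs
    )


def build_gene_network(
    master: MasterNetwork, annotation: GenomeAnnotation
) -> GeneNetwork:
    """Map every master link onto feature pairs and accumulate weights."""
    net = GeneNetwork(group=master.group)
    for (i, j) in master.position_pairs:
        for fa in annotation.features_at(i):
            for fb in annotation.features_at(j):
                key = _pair(fa, fb)
                net.weights[key] = net.weights.get(key, 0) + 1
    return net
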