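"""Co-occurrence frequency, per-sample two-node motifs, and master networks.

For a pair of variable sites i and j and nucleotides x, y, the co-occurrence
frequency is

    C(i, j) = N(x_i y_j)^2 / (N(x_i) * N(y_j))

where N(x_i y_j) counts samples carrying x at i *and* y at j, and N(x_i),
N(y_j) count the carriers of each allele separately. C ranges from 0 (never
jointly carried) to 1, and C = 1 exactly when the carrier sets of x-at-i and
y-at-j coincide (perfect co-occurrence). Samples with missing data ('N' or
'-') at either position are excluded from all three counts: ambiguity is
missingness, not evidence.

Per sample, a motif network is built over the sites where that sample
carries a *minor* allele; an edge joins two such sites when C for the
sample's allele pair reaches the threshold C_th (the analysis default is
C_th = 1, i.e. perfect co-occurrence only). The per-sample networks of one
altitude group are merged (set union, deduplicated) into the group's master
network, whose node universe is all variable sites of the group — sites in
no motif stay as isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AlignedCohort, NUCLEOTIDES
from .annotation import GenomeAnnotation
from .errors import GroupError, UndefinedAlleleError
from .sites import VariableSite, extract_variable_sites

#: key type for allele-level edges: (position_i, position_j, allele_i, allele_j), i < j
EdgeKey = tuple[int, int, str, str]


@dataclass(frozen=True)
class CooccurrenceEdge:
    """An allele-level co-occurrence link between two variable sites."""

    position_i: int
    position_j: int
    allele_i: str
    allele_j: str
    c: float
    support: tuple[str, ...]  # sample ids carrying both minor alleles

    @property
    def key(self) -> EdgeKey:
        return (self.position_i, self.position_j, self.allele_i, self.allele_j)


def cooccurrence_frequency(
    matrix: np.ndarray, col_i: int, col_j: int, x: str, y: str
) -> float:
    """Evaluate C for alleles *x* at column *col_i* and *y* at *col_j*.

    *matrix* is one group's ``(samples, columns)`` character alignment.
    Samples with missing data at either column are excluded from every
    count. Raises :class:`UndefinedAlleleError` if either allele is absent
    among the remaining samples.
    """
    if col_i == col_j:
        raise ValueError("co-occurrence needs two distinct positions")
    for a in (x, y):
        if a not in NUCLEOTIDES:
            raise ValueError(f"not a nucleotide: {a!r}")
    a_i, a_j = matrix[:, col_i], matrix[:, col_j]
    valid = np.isin(a_i, NUCLEOTIDES) & np.isin(a_j, NUCLEOTIDES)
    n_x = int(((a_i == x) & valid).sum())
    n_y = int(((a_j == y) & valid).sum())
    if n_x == 0 or n_y == 0:
        raise UndefinedAlleleError(
            f"allele {x}@col{col_i} or {y}@col{col_j} absent after missing-data exclusion"
        )
    n_xy = int(((a_i == x) & (a_j == y) & valid).sum())
    return n_xy * n_xy / (n_x * n_y)


class GroupContext:
    """Cached per-group view: matrix, variable sites, and C evaluations."""

    def __init__(
        self,
        cohort: AlignedCohort,
        group: int,
        sites: list[VariableSite] | None = None,
        annotation: GenomeAnnotation | None = None,
    ):
        self.group = group
        self.sample_ids = cohort.group_sample_ids(group)
        self.matrix = cohort.group_matrix(group)
        self.sites = (
            sites if sites is not None else extract_variable_sites(cohort, group, annotation)
        )
        positions = [s.position for s in self.sites]
        cols = []
        for p in positions:
            hit = np.nonzero(cohort.column_to_ref == p)[0]
            cols.append(int(hit[0]))
        self.col_of: dict[int, int] = dict(zip(positions, cols))
        self.site_of: dict[int, VariableSite] = {s.position: s for s in self.sites}
        self._c_cache: dict[EdgeKey, float] = {}
        self._support_cache: dict[EdgeKey, tuple[str, ...]] = {}

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]

    def c_value(self, key: EdgeKey) -> float:
        if key not in self._c_cache:
            i, j, x, y = key
            self._c_cache[key] = cooccurrence_frequency(
                self.matrix, self.col_of[i], self.col_of[j], x, y
            )
        return self._c_cache[key]

    def support(self, key: EdgeKey) -> tuple[str, ...]:
        if key not in self._support_cache:
            i, j, x, y = key
            a_i = self.matrix[:, self.col_of[i]]
            a_j = self.matrix[:, self.col_of[j]]
            both = (a_i == x) & (a_j == y)
            self._support_cache[key] = tuple(
                s for s, b in zip(self.sample_ids, both) if b
            )
        return self._support_cache[key]


@dataclass
class SampleMotifs:
    """One sample's two-node motif network (allele-level edges)."""

    sample_id: str
    group: int
    nodes: set[int]  # positions where the sample carries a minor allele
    edges: set[EdgeKey]


def build_sample_motifs(
    ctx: GroupContext, sample_index: int, c_th: float = 1.0
) -> SampleMotifs:
    """Motif network of one sample: minor-allele sites joined where C >= C_th.

    Only minor alleles seed motifs; the major-allele background never forms
    edges. A sample with no minor alleles yields an empty network.
    """
    row = ctx.matrix[sample_index]
    carried: list[tuple[int, str]] = []
    for site in ctx.sites:
        allele = str(row[ctx.col_of[site.position]])
        if allele in site.minor_alleles:
            carried.append((site.position, allele))
    edges: set[EdgeKey] = set()
    for (pi, xi), (pj, xj) in combinations(carried, 2):
        key: EdgeKey = (pi, pj, xi, xj) if pi < pj else (pj, pi, xj, xi)
        if ctx.c_value(key) >= c_th:
            edges.add(key)
    return SampleMotifs(
        sample_id=ctx.sample_ids[sample_index],
        group=ctx.group,
        nodes={p for p, _ in carried},
        edges=edges,
    )


@dataclass
class MasterNetwork:
    """Per-group union of sample motif networks over all variable sites.

    Edges are stored at allele level (position pair + allele pair); the
    node-level view collapses parallel allele edges, and Nc counts distinct
    position pairs, keeping the graph simple.
    """

    group: int
    nodes: set[int]
    edges: dict[EdgeKey, CooccurrenceEdge] = field(default_factory=dict)
    c_th: float = 1.0

    @property
    def position_pairs(self) -> set[tuple[int, int]]:
        return {(k[0], k[1]) for k in self.edges}

    @property
    def n_edges(self) -> int:
        """Nc: number of node-level (position-pair) links."""
        return len(self.position_pairs)

    @property
    def mean_degree(self) -> float:
        return average_degree(self)

    def graph(self) -> nx.Graph:
        """Node-level simple graph; allele edges collapse onto position pairs."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for edge in self.edges.values():
            i, j = edge.position_i, edge.position_j
            if g.has_edge(i, j):
                g[i][j]["alleles"].append((edge.allele_i, edge.allele_j))
            else:
                g.add_edge(i, j, c=edge.c, alleles=[(edge.allele_i, edge.allele_j)])
        return g

    def degree(self, position: int) -> int:
        if position not in self.nodes:
            raise KeyError(f"position {position} is not a node of group {self.group}")
        return sum(1 for (i, j) in self.position_pairs if position in (i, j))

    def connected_nodes(self) -> set[int]:
        return {p for pair in self.position_pairs for p in pair}

    def isolated_nodes(self) -> set[int]:
        return self.nodes - self.connected_nodes()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pos_i": e.position_i,
                "pos_j": e.position_j,
                "allele_i": e.allele_i,
                "allele_j": e.allele_j,
                "c": e.c,
                "support": ",".join(e.support),
            }
            for e in sorted(self.edges.values(), key=lambda e: e.key)
        ]
        return pd.DataFrame(
            rows, columns=["pos_i", "pos_j", "allele_i", "allele_j", "c", "support"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph()
        for _, _, data in g.edges(data=True):
            data["alleles"] = ";".join(f"{a}{b}" for a, b in data["alleles"])
        nx.write_graphml(g, str(path))


def merge_master(
    motifs: list[SampleMotifs], ctx: GroupContext, c_th: float = 1.0
) -> MasterNetwork:
    """Union the per-sample motif networks of one group, deduplicated."""
    groups = {m.group for m in motifs}
    if len(groups) > 1:
        raise GroupError(f"cannot merge motifs from different groups: {sorted(groups)}")
    master = MasterNetwork(group=ctx.group, nodes=set(ctx.positions), c_th=c_th)
    for m in motifs:
        for key in m.edges:
            if key not in master.edges:
                master.edges[key] = CooccurrenceEdge(
                    *key, c=ctx.c_value(key), support=ctx.support(key)
                )
    return master


def build_master_network(
    cohort: AlignedCohort,
    group: int,
    c_th: float = 1.0,
    annotation: GenomeAnnotation | None = None,
    sites: list[VariableSite] | None = None,
) -> tuple[GroupContext, MasterNetwork]:
    """Extract sites, build every sample's motifs, and merge the master network."""
    ctx = GroupContext(cohort, group, sites=sites, annotation=annotation)
    motifs = [build_sample_motifs(ctx, k, c_th) for k in range(len(ctx.sample_ids))]
    return ctx, merge_master(motifs, ctx, c_th)


def build_all_masters(
    cohort: AlignedCohort,
    c_th: float = 1.0,
    annotation: GenomeAnnotation | None = None,
) -> dict[int, MasterNetwork]:
    """Master networks for every altitude group present in the cohort."""
    return {
        g: build_master_network(cohort, g, c_th, annotation)[1]
        for g in cohort.group_labels
    }


def average_degree(master: MasterNetwork, universe: str = "all") -> float:
    """<k> = 2 Nc / |nodes|.

    ``universe="all"`` (default) divides by every variable site of the
    group, isolated nodes included; ``universe="connected"`` divides by
    degree >= 1 nodes only. Both are reported in summaries because tabulated
    values in the literature are ambiguous on this point.
    """
    if universe == "all":
        n = len(master.nodes)
    elif universe == "connected":
        n = len(master.connected_nodes())
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if n == 0:
        raise ValueError("average degree undefined on an empty node set")
    return 2.0 * master.n_edges / n
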