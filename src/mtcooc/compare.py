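"""Between-group comparisons: proportion Z-tests, Jaccard similarity, clustering.

The difference in the proportion of local connected nodes between two
altitude groups is assessed with a two-proportion Z-test,

    Z = (p_i - p_j) / sqrt( p (1 - p) (1/n_i + 1/n_j) )

with p the pooled proportion over both groups and n the groups' total
variable-site counts; significance uses the two-sided standard-normal
critical value 1.96 at alpha = 0.05.

Group similarity is the Jaccard coefficient of the groups' node sets,
J = |intersection| / |union|, and groups are clustered by agglomerative
(UPGMA by default) linkage on the distance 1 - J, yielding a dendrogram
serialized as Newick.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .categorize import NodeCatalog
from .errors import DegenerateVarianceError, GroupError

#: two-sided standard-normal critical value at alpha = 0.05
ALPHA = 0.05


def z_critical(alpha: float = ALPHA) -> float:
    """Two-sided standard-normal critical value (1.96 at alpha = 0.05)."""
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class ProportionTest:
    group_i: int
    group_j: int
    p_i: float
    p_j: float
    pooled: float
    n_i: int
    n_j: int
    z: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def two_proportion_z_from_counts(
    k_i: int, n_i: int, k_j: int, n_j: int, group_i: int = 0, group_j: int = 1
) -> ProportionTest:
    """Two-proportion Z-test from success/total counts of two groups."""
    if n_i < 1 or n_j < 1:
        raise GroupError("both groups need at least one variable site")
    p_i, p_j = k_i / n_i, k_j / n_j
    pooled = (k_i + k_j) / (n_i + n_j)
    if pooled in (0.0, 1.0):
        raise DegenerateVarianceError(
            f"pooled proportion {pooled}: zero variance, Z undefined"
        )
    a, b = 1.0 / n_i, 1.0 / n_j
    z = (p_i - p_j) / np.sqrt(pooled * (1.0 - pooled) * (a + b))
    p_value = 2.0 * stats.norm.sf(abs(z))
    return ProportionTest(
        group_i=group_i, group_j=group_j, p_i=p_i, p_j=p_j,
        pooled=pooled, n_i=n_i, n_j=n_j, z=float(z), p_value=float(p_value),
    )


def two_proportion_z(
    catalog: NodeCatalog, group_i: int, group_j: int
) -> ProportionTest:
    """Z-test on local-connected-node proportions of two altitude groups."""
    k_i = len(catalog.nodes(group_i, connectivity="connected", scope="local"))
    k_j = len(catalog.nodes(group_j, connectivity="connected", scope="local"))
    n_i = len(catalog.nodes(group_i))
    n_j = len(catalog.nodes(group_j))
    return two_proportion_z_from_counts(k_i, n_i, k_j, n_j, group_i, group_j)


def all_proportion_tests(catalog: NodeCatalog) -> pd.DataFrame:
    """Z-test for every group pair; degenerate pairs (pooled proportion 0 or
    1) are reported with NaN statistics instead of aborting."""
    rows = []
    for a in catalog.groups:
        for b in catalog.groups:
            if a >= b:
                continue
            try:
                t = two_proportion_z(catalog, a, b)
                row = {
                    "group_i": a, "group_j": b, "p_i": t.p_i, "p_j": t.p_j,
                    "z": t.z, "p_value": t.p_value, "significant": t.significant,
                }
            except DegenerateVarianceError:
                row = {
                    "group_i": a, "group_j": b,
                    "p_i": float("nan"), "p_j": float("nan"),
                    "z": float("nan"), "p_value": float("nan"), "significant": False,
                }
            rows.append(row)
    return pd.DataFrame(rows)


def jaccard(nodes_i: set[int], nodes_j: set[int]) -> float:
    """|intersection| / |union| of two node sets."""
    if not nodes_i and not nodes_j:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(nodes_i & nodes_j) / len(nodes_i | nodes_j)


def group_node_sets(
    catalog: NodeCatalog,
    node_set: str = "connected",
    exclude_global: bool = False,
) -> dict[int, set[int]]:
    """Per-group node sets for similarity.

    ``node_set`` is ``"connected"`` (default: degree >= 1 sites) or
    ``"all"`` (every variable site). ``exclude_global=True`` removes
    scope-global positions, restricting similarity to partially shared
    (mixed) structure; both conventions appear in the literature, so the
    choice is explicit rather than implied.
    """
    if node_set not in ("connected", "all"):
        raise ValueError(f"unknown node_set {node_set!r}")
    out = {}
    for g in catalog.groups:
        nodes = (
            catalog.nodes(g, connectivity="connected")
            if node_set == "connected"
            else catalog.nodes(g)
        )
        if exclude_global:
            nodes = {p for p in nodes if catalog.scope.get(p) != "global"}
        out[g] = nodes
    return out


def jaccard_matrix(node_sets: dict[int, set[int]]) -> pd.DataFrame:
    """Symmetric Jaccard matrix over all group pairs (diagonal 1)."""
    groups = sorted(node_sets)
    mat = np.eye(len(groups))
    for a_idx, a in enumerate(groups):
        for b_idx, b in enumerate(groups):
            if a_idx < b_idx:
                j = jaccard(node_sets[a], node_sets[b])
                mat[a_idx, b_idx] = mat[b_idx, a_idx] = j
    return pd.DataFrame(mat, index=groups, columns=groups)


@dataclass
class SimilarityResult:
    jaccard: pd.DataFrame
    linkage_method: str
    linkage: np.ndarray
    tree: TreeNode

    @property
    def newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def first_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf-name sets of the two subtrees under the root."""
        children = self.tree.children
        if len(children) != 2:
            raise ValueError("dendrogram root is not binary")
        return tuple(
            frozenset(leaf.name for leaf in child.tips()) if child.children
            else frozenset([child.name])
            for child in children
        )


def similarity_dendrogram(
    jaccard_df: pd.DataFrame,
    linkage_method: str = "average",
    label_prefix: str = "group",
) -> SimilarityResult:
    """Agglomerative clustering of groups on distance 1 - J.

    Average linkage (UPGMA) by default; the tree is rooted at the last
    merge and serialized as Newick with ``group<g>`` leaf labels. Leaf
    order is deterministic for a given matrix.
    """
    mat = jaccard_df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("Jaccard matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("Jaccard matrix diagonal must be 1")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method=linkage_method)
    labels = [f"{label_prefix}{g}" for g in jaccard_df.index]
    tree = TreeNode.from_linkage_matrix(link, labels)
    return SimilarityResult(
        jaccard=jaccard_df, linkage_method=linkage_method, linkage=link, tree=tree
    )
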