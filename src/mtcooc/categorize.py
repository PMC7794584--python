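"""Node categorization across altitude groups.

Each group's variable sites split two ways:

* connectivity — *connected* (degree >= 1 in the group's master network)
  vs *isolated* (degree 0);
* scope — *local* (a variable site in exactly one group), *mixed* (in
  several but not all groups), *global* (in every group).

Scope is defined by variable-site presence, not by connectivity, and the
two axes are tracked independently; convenience accessors intersect them
(e.g. the "global connected" nodes — positions connected in every group —
a tiny set in real mitochondrial cohorts, dominated by known haplogroup
markers such as 16327).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation import GenomeAnnotation
from .cooccurrence import MasterNetwork

CONNECTIVITIES = ("connected", "isolated")
SCOPES = ("local", "mixed", "global")


@dataclass
class NodeCatalog:
    """Cross-group index of variable sites with connectivity and scope labels."""

    groups: list[int]
    presence: dict[int, set[int]]  # position -> groups where it is a variable site
    connectivity: dict[int, dict[int, str]]  # group -> position -> connected/isolated
    scope: dict[int, str] = field(default_factory=dict)  # position -> local/mixed/global

    def nodes(
        self, group: int, connectivity: str | None = None, scope: str | None = None
    ) -> set[int]:
        """One group's variable sites, optionally filtered on either axis."""
        conn = self.connectivity[group]
        out = set(conn)
        if connectivity is not None:
            if connectivity not in CONNECTIVITIES:
                raise ValueError(f"unknown connectivity {connectivity!r}")
            out = {p for p in out if conn[p] == connectivity}
        if scope is not None:
            if scope not in SCOPES:
                raise ValueError(f"unknown scope {scope!r}")
            out = {p for p in out if self.scope.get(p) == scope}
        return out

    def global_connected(self) -> set[int]:
        """Positions connected in *every* group."""
        sets = [
            {p for p, c in self.connectivity[g].items() if c == "connected"}
            for g in self.groups
        ]
        return set.intersection(*sets) if sets else set()

    def global_isolated(self) -> set[int]:
        """Scope-global positions isolated in every group."""
        out = {p for p, s in self.scope.items() if s == "global"}
        for g in self.groups:
            out &= {p for p, c in self.connectivity[g].items() if c == "isolated"}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for p in sorted(self.connectivity[g]):
                rows.append(
                    {
                        "position": p,
                        "group": g,
                        "connectivity": self.connectivity[g][p],
                        "scope": self.scope.get(p, ""),
                    }
                )
        return pd.DataFrame(rows, columns=["position", "group", "connectivity", "scope"])

    def summary(self) -> pd.DataFrame:
        """Per-group percentage breakdown of scope within each connectivity class."""
        rows = []
        for g in self.groups:
            n_total = len(self.nodes(g))
            row: dict[str, float | int] = {"group": g, "n_variable_sites": n_total}
            for conn in CONNECTIVITIES:
                in_class = self.nodes(g, connectivity=conn)
                row[f"n_{conn}"] = len(in_class)
                for sc in SCOPES:
                    n = len(self.nodes(g, connectivity=conn, scope=sc))
                    row[f"{conn}_{sc}_pct"] = (
                        100.0 * n / len(in_class) if in_class else float("nan")
                    )
            rows.append(row)
        return pd.DataFrame(rows)


def categorize_nodes(masters: dict[int, MasterNetwork]) -> NodeCatalog:
    """Build the :class:`NodeCatalog` from every group's master network.

    With a single group, scope cannot be defined and only the
    connected/isolated split is produced (with a warning).
    """
    groups = sorted(masters)
    presence: dict[int, set[int]] = {}
    connectivity: dict[int, dict[int, str]] = {}
    for g in groups:
        master = masters[g]
        connected = master.connected_nodes()
        connectivity[g] = {
            p: ("connected" if p in connected else "isolated") for p in master.nodes
        }
        for p in master.nodes:
            presence.setdefault(p, set()).add(g)
    catalog = NodeCatalog(groups=groups, presence=presence, connectivity=connectivity)
    if len(groups) < 2:
        warnings.warn(
            "scope (local/mixed/global) needs at least two groups; "
            "catalog restricted to connected/isolated",
            stacklevel=2,
        )
        return catalog
    n_groups = len(groups)
    for p, where in presence.items():
        if len(where) == n_groups:
            catalog.scope[p] = "global"
        elif len(where) == 1:
            catalog.scope[p] = "local"
        else:
            catalog.scope[p] = "mixed"
    return catalog


def local_pair_fraction(
    catalog: NodeCatalog, master: MasterNetwork
) -> float | None:
    """Percentage of master edges whose *both* endpoints are local nodes.

    Returns ``None`` when the master network has no edges (undefined).
    """
    pairs = master.position_pairs
    if not pairs:
        return None
    local = catalog.nodes(master.group, scope="local")
    n_local_pairs = sum(1 for (i, j) in pairs if i in local and j in local)
    return 100.0 * n_local_pairs / len(pairs)


def neighbors_of(
    master: MasterNetwork,
    position: int,
    annotation: GenomeAnnotation | None = None,
) -> list[tuple[int, list[str]]]:
    """Adjacency of one node with each neighbour's feature annotation.

    Supports marker-centred reporting (e.g. the high-altitude markers 3010,
    3394, 7697 and the ancestral 10398).
    """
    if position not in master.nodes:
        raise KeyError(f"position {position} is not a node of group {master.group}")
    neighbours = sorted(
        (j if i == position else i)
        for (i, j) in master.position_pairs
        if position in (i, j)
    )
    return [
        (n, annotation.features_at(n) if annotation else [])
        for n in neighbours
    ]
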