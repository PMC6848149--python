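"""Multi-level community hierarchy by recursive modularity maximization.

The network is partitioned with the Louvain method; each detected community
is then re-partitioned on its induced subgraph, and so on recursively. A
community takes part in the recursion only while it can still host the
triangle motif G(3,3) — three nodes, three edges — the minimal densely
connected unit. Recursion for a branch stops when the community has no
triangle, cannot be split further (Louvain returns a single community), is
smaller than ``min_size``, or the level cap is reached. The result is a
tree of nested communities whose per-level mean modularity typically decays
toward zero at the motif level.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Partition",
    "Community",
    "HierarchyTree",
    "louvain",
    "modularity",
    "count_triangles",
    "qualifies",
    "build_hierarchy",
    "level_summary",
]


@dataclass(frozen=True)
class Partition:
    """A flat partition of a graph: node→community label, its modularity Q,
    the hierarchy level it was computed for and the seed used."""

    labels: dict[str, int]
    q: float
    level: int
    seed: int
    resolution: float = 1.0

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[lab] for lab in sorted(out)]


def modularity(net: nx.Graph, labels: Mapping[str, int]) -> float:
    """Newman–Girvan modularity Q = Σ_c (e_c/m − (d_c/2m)²).

    Raises if any network node is unlabeled.
    """
    missing = set(net.nodes) - set(labels)
    if missing:
        raise ValueError(f"modularity: {len(missing)} unlabeled node(s), e.g. {sorted(missing)[:3]}")
    groups: dict[int, set[str]] = {}
    for node in net.nodes:
        groups.setdefault(labels[node], set()).add(node)
    return float(nx.community.modularity(net, list(groups.values())))


def _canonical_communities(comms: list[set[str]]) -> list[list[str]]:
    """Sort communities (largest first, then lexicographic) for stable labels."""
    return sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))


def louvain(
    net: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 1,
) -> Partition:
    """Louvain modularity maximization, deterministic for a given seed.

    With ``restarts`` > 1 the partition with the best Q over seeds
    ``seed .. seed+restarts-1`` is returned. The graph is relabelled to
    integers (sorted node order) internally so the outcome cannot depend
    on string-hash ordering.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("louvain: empty network")
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    H = nx.Graph()
    H.add_nodes_from(range(len(nodes)))
    H.add_edges_from((idx[u], idx[v]) for u, v in net.edges())

    best: Partition | None = None
    for s in range(seed, seed + max(1, restarts)):
        comms_int = nx.community.louvain_communities(H, resolution=resolution, seed=s)
        comms = [{nodes[i] for i in c} for c in comms_int]
        labels = {
            node: lab
            for lab, comm in enumerate(_canonical_communities(comms))
            for node in comm
        }
        q = modularity(net, labels)
        if best is None or q > best.q:
            best = Partition(labels=labels, q=q, level=1, seed=s, resolution=resolution)
    assert best is not None
    return best


def count_triangles(net: nx.Graph) -> int:
    """Number of distinct 3-cliques (triangle motifs G(3,3))."""
    return sum(nx.triangles(net).values()) // 3


def qualifies(net: nx.Graph) -> bool:
    """True iff the (sub)network contains at least one triangle motif."""
    return any(t > 0 for t in nx.triangles(net).values())


@dataclass
class Community:
    """One community in the hierarchy.

    ``level`` 0 is the root (whole network). ``sub_q`` is the modularity of
    the partition that split this community into its children (None for
    leaves). ``qualifies`` records whether the community contains a triangle.
    """

    id: str
    level: int
    nodes: frozenset[str]
    qualifies: bool
    sub_q: float | None = None
    parent: str | None = None
    children: list["Community"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "level": self.level,
            "n_nodes": len(self.nodes),
            "nodes": sorted(self.nodes),
            "qualifies": self.qualifies,
            "Q": self.sub_q,
            "children": [c.to_dict() for c in self.children],
        }


class HierarchyTree:
    """Tree of nested communities produced by :func:`build_hierarchy`."""

    def __init__(self, net: nx.Graph, root: Community, seed: int):
        self.net = net
        self.root = root
        self.seed = seed
        self._by_id: dict[str, Community] = {}
        for c in self.walk():
            self._by_id[c.id] = c

    def walk(self) -> Iterator[Community]:
        stack = [self.root]
        while stack:
            c = stack.pop()
            yield c
            stack.extend(reversed(c.children))

    def __getitem__(self, cid: str) -> Community:
        return self._by_id[cid]

    @property
    def max_depth(self) -> int:
        """Deepest level attained anywhere in the tree (root = level 0)."""
        return max(c.level for c in self.walk())

    def communities_at(self, level: int) -> list[Community]:
        return sorted((c for c in self.walk() if c.level == level), key=lambda c: c.id)

    def chain(self, node: str) -> list[Community]:
        """Nested communities containing ``node``, from level 1 downwards."""
        if node not in self.root.nodes:
            raise KeyError(f"node {node!r} not in hierarchy")
        out: list[Community] = []
        cur = self.root
        while cur.children:
            nxt = next((c for c in cur.children if node in c.nodes), None)
            if nxt is None:
                break
            out.append(nxt)
            cur = nxt
        return out

    def membership_table(self) -> pd.DataFrame:
        """Flat node table: one column of community IDs per level."""
        depth = self.max_depth
        rows = {}
        for node in sorted(self.root.nodes):
            chain = self.chain(node)
            row = {f"level{l}": "" for l in range(1, depth + 1)}
            for c in chain:
                row[f"level{c.level}"] = c.id
            rows[node] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "node"
        return df

    def to_json(self, path: str | pathlib.Path | None = None) -> str:
        payload = json.dumps(
            {"seed": self.seed, "max_depth": self.max_depth, "root": self.root.to_dict()},
            indent=1,
        )
        if path is not None:
            pathlib.Path(path).write_text(payload + "\n")
        return payload


def build_hierarchy(
    net: nx.Graph,
    seed: int = 0,
    max_levels: int = 10,
    min_size: int = 3,
    resolution: float = 1.0,
    restarts: int = 1,
) -> HierarchyTree:
    """Recursively partition ``net`` down to the triangle-motif level.

    Level-1 communities come from Louvain on the full network; each
    qualifying community with at least ``min_size`` nodes is re-clustered
    on its induced subgraph (inter-community edges are ignored below the
    parent level), producing the next level, until no triangle remains, no
    further split is possible, or ``max_levels`` is reached.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("build_hierarchy: empty network")
    root = Community(
        id="root", level=0, nodes=frozenset(net.nodes), qualifies=qualifies(net)
    )

    def split(parent: Community, sub: nx.Graph) -> None:
        if parent.level >= max_levels:
            return
        is_root = parent.id == "root"
        if not is_root and (len(parent.nodes) < min_size or not parent.qualifies):
            return
        part = louvain(sub, seed=seed, resolution=resolution, restarts=restarts)
        comms = part.communities()
        # level 1 always exists: an unsplittable root yields one level-1 leaf
        if len(comms) <= 1 and not is_root:
            return
        parent.sub_q = part.q
        prefix = "C" if parent.id == "root" else parent.id + "."
        for i, cnodes in enumerate(_canonical_communities(comms)):
            childgraph = sub.subgraph(cnodes)
            child = Community(
                id=f"{prefix}{i}",
                level=parent.level + 1,
                nodes=frozenset(cnodes),
                qualifies=qualifies(childgraph),
                parent=parent.id,
            )
            parent.children.append(child)
            split(child, sub.subgraph(cnodes))

    split(root, net)
    return HierarchyTree(net, root, seed)


def level_summary(tree: HierarchyTree) -> pd.DataFrame:
    """Per-level community counts and mean modularity.

    ``mean_Q`` at level ℓ is the mean modularity of the partitions that
    produced the level-ℓ communities (the per-level Q, which typically
    decreases toward the motif level). ``n_reaching_deepest`` counts the
    level-ℓ communities whose subtree attains the tree's maximum depth.
    """
    depth = tree.max_depth
    if depth == 0:
        return pd.DataFrame(
            [{"level": 0, "n_communities": 1, "n_qualifying": int(tree.root.qualifies),
              "mean_Q": float("nan"), "n_reaching_deepest": 1}]
        ).set_index("level")

    def subtree_depth(c: Community) -> int:
        return max(c.level, *(subtree_depth(ch) for ch in c.children)) if c.children else c.level

    rows = []
    for level in range(1, depth + 1):
        comms = tree.communities_at(level)
        parents = {c.parent for c in comms}
        qs = [tree[p].sub_q for p in parents if p is not None and tree[p].sub_q is not None]
        rows.append(
            {
                "level": level,
                "n_communities": len(comms),
                "n_qualifying": sum(c.qualifies for c in comms),
                "mean_Q": float(pd.Series(qs).mean()) if qs else float("nan"),
                "n_reaching_deepest": sum(subtree_depth(c) == depth for c in comms),
            }
        )
    return pd.DataFrame(rows).set_index("level")
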