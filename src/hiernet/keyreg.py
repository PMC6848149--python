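"""Hub selection, cross-level tracing and key-regulator identification.

Hubs are the highest-degree nodes (by an absolute degree threshold or a
top-n cut). Each hub is traced through its chain of nested communities in
the hierarchy; a hub is a *key regulator* when that chain reaches the
deepest level of the tree and every community along it contains a triangle
motif — the hub persists inside cohesive modules at every level of
organization, forming part of the network's backbone.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from hiernet.hierarchy import HierarchyTree

__all__ = [
    "TraceRecord",
    "select_hubs",
    "trace_hubs",
    "identify_key_regulators",
    "motif_partners",
    "key_regulator_table",
    "write_motif_partners",
]


@dataclass(frozen=True)
class TraceRecord:
    """Trace of one hub through the community hierarchy."""

    hub: str
    degree: int
    chain: tuple[str, ...]            # community IDs, level 1 downward
    qualifies_chain: tuple[bool, ...]
    depth: int                        # deepest level the chain reaches
    terminal_nodes: frozenset[str]    # members of the terminal community
    is_key_regulator: bool

    @property
    def qualifies_all(self) -> bool:
        return all(self.qualifies_chain)


def select_hubs(
    net: nx.Graph,
    min_degree: int | None = None,
    top_n: int | None = None,
) -> list[str]:
    """Select hub nodes, sorted by degree descending (ties by node ID).

    Exactly one of ``min_degree`` (keep nodes with k ≥ threshold) or
    ``top_n`` (keep the n highest-degree nodes) must be given.

    Raises
    ------
    ValueError
        If both/neither selector is given or the selection is empty.
    """
    if (min_degree is None) == (top_n is None):
        raise ValueError("select_hubs: give exactly one of min_degree or top_n")
    ranked = sorted(net.nodes, key=lambda n: (-net.degree(n), n))
    if min_degree is not None:
        hubs = [n for n in ranked if net.degree(n) >= min_degree]
    else:
        hubs = ranked[: top_n]
    if not hubs:
        raise ValueError("select_hubs: empty selection (threshold above max degree?)")
    return hubs


def trace_hubs(tree: HierarchyTree, hubs: Iterable[str]) -> dict[str, TraceRecord]:
    """Trace each hub through its nested community chain.

    ``is_key_regulator`` is filled in against the tree's global maximum
    depth; see :func:`identify_key_regulators` for the laxer per-branch mode.
    """
    max_depth = tree.max_depth
    out: dict[str, TraceRecord] = {}
    for hub in hubs:
        if hub not in tree.root.nodes:
            raise KeyError(f"trace_hubs: hub {hub!r} not in hierarchy")
        chain = tree.chain(hub)
        terminal = chain[-1].nodes if chain else tree.root.nodes
        depth = chain[-1].level if chain else 0
        quals = tuple(c.qualifies for c in chain)
        out[hub] = TraceRecord(
            hub=hub,
            degree=tree.net.degree(hub),
            chain=tuple(c.id for c in chain),
            qualifies_chain=quals,
            depth=depth,
            terminal_nodes=frozenset(terminal),
            is_key_regulator=bool(depth == max_depth and all(quals) and chain),
        )
    return out


def identify_key_regulators(
    traces: Mapping[str, TraceRecord],
    mode: str = "global_max_depth",
) -> list[str]:
    """Hubs whose community chain persists, fully qualifying, to the deepest level.

    ``mode="global_max_depth"`` (default) requires the chain to reach the
    maximum depth attained anywhere in the tree; ``mode="branch_max_depth"``
    only requires every community on the chain to qualify (the hub persists
    as deep as its own branch goes). Result sorted by degree descending,
    ties by node ID.
    """
    if not traces:
        raise ValueError("identify_key_regulators: no traces")
    if mode == "global_max_depth":
        keep = [t for t in traces.values() if t.is_key_regulator]
    elif mode == "branch_max_depth":
        keep = [t for t in traces.values() if t.chain and t.qualifies_all]
    else:
        raise ValueError(f"identify_key_regulators: unknown mode {mode!r}")
    return [t.hub for t in sorted(keep, key=lambda t: (-t.degree, t.hub))]


def motif_partners(
    tree: HierarchyTree, key_regs: Iterable[str]
) -> dict[str, dict]:
    """Partners of each key regulator in its terminal (deepest) community.

    Returns, per key regulator, the other members of its terminal community
    and the edges among all terminal-community members.
    """
    out: dict[str, dict] = {}
    for kr in key_regs:
        chain = tree.chain(kr)
        members = sorted(chain[-1].nodes) if chain else sorted(tree.root.nodes)
        sub = tree.net.subgraph(members)
        out[kr] = {
            "partners": [m for m in members if m != kr],
            "edges": sorted(tuple(sorted(e)) for e in sub.edges()),
        }
    return out


def key_regulator_table(traces: Mapping[str, TraceRecord], key_regs: Iterable[str]) -> pd.DataFrame:
    """Report table: one row per hub with its trace summary."""
    key_set = set(key_regs)
    rows = []
    for t in sorted(traces.values(), key=lambda t: (-t.degree, t.hub)):
        rows.append(
            {
                "node": t.hub,
                "degree": t.degree,
                "depth_reached": t.depth,
                "qualifies_all": t.qualifies_all,
                "is_key_regulator": t.hub in key_set,
                "terminal_community_size": len(t.terminal_nodes),
            }
        )
    return pd.DataFrame(rows).set_index("node")


def write_motif_partners(partners: Mapping[str, dict], path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(json.dumps(partners, indent=1, sort_keys=True) + "\n")
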