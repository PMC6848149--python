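"""Reading, curating and writing networks and per-node result tables.

Networks are held as :class:`networkx.Graph` objects with string node
identifiers, no self-loops and no parallel edges. Node IDs are opaque,
case-sensitive strings; no gene-symbol normalization is attempted.
"""

from __future__ import annotations

import logging
import pathlib

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_edge_list",
    "read_graphml",
    "write_graphml",
    "write_edge_list",
    "curate",
    "write_node_table",
    "read_node_table",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as a network."""


def read_edge_list(
    path: str | pathlib.Path,
    delimiter: str | None = None,
    comment_prefix: str = "#",
) -> nx.Graph:
    """Read an undirected simple graph from a two-column edge list.

    Parameters
    ----------
    path
        Text file with one edge per line. Extra columns beyond the first two
        are ignored.
    delimiter
        Field separator; ``None`` splits on any whitespace (covers both
        space- and tab-separated files).
    comment_prefix
        Lines starting with this prefix are skipped.

    Self-loops and duplicate edges are dropped silently; the counts are
    emitted via logging.

    Raises
    ------
    ParseError
        If a non-comment line has fewer than two fields, or the file
        contains no edges at all.
    """
    path = pathlib.Path(path)
    G: nx.Graph = nx.Graph(name=path.stem)
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            u, v = fields[0], fields[1]
            n_lines += 1
            if u == v:
                n_self += 1
                continue
            if G.has_edge(u, v):
                n_dup += 1
                continue
            G.add_edge(u, v)
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_self or n_dup:
        logger.info(
            "read_edge_list(%s): dropped %d self-loop(s), %d duplicate edge(s)",
            path.name, n_self, n_dup,
        )
    logger.info(
        "read_edge_list(%s): %d nodes, %d edges", path.name,
        G.number_of_nodes(), G.number_of_edges(),
    )
    return G


def read_graphml(path: str | pathlib.Path) -> nx.Graph:
    """Read an undirected network from GraphML.

    The node's ``name`` attribute is used as its identifier when every node
    carries one; otherwise the GraphML node id is used. Self-loops and
    parallel edges are dropped with logged counts.

    Raises
    ------
    ParseError
        If the file declares a directed graph (convert explicitly first)
        or is not well-formed XML.
    """
    path = pathlib.Path(path)
    try:
        raw = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors vary by backend
        raise ParseError(f"{path}: not parseable as GraphML ({exc})") from exc
    if raw.is_directed():
        raise ParseError(
            f"{path}: declares a directed graph; convert to undirected explicitly "
            "before analysis"
        )
    if all("name" in d for _, d in raw.nodes(data=True)) and raw.number_of_nodes() > 0:
        raw = nx.relabel_nodes(raw, {n: str(d["name"]) for n, d in raw.nodes(data=True)})
    G: nx.Graph = nx.Graph(name=path.stem)
    G.add_nodes_from(str(n) for n in raw.nodes)
    n_self = 0
    for u, v in raw.edges():
        u, v = str(u), str(v)
        if u == v:
            n_self += 1
            continue
        G.add_edge(u, v)
    if n_self:
        logger.info("read_graphml(%s): dropped %d self-loop(s)", path.name, n_self)
    return G


def write_graphml(net: nx.Graph, path: str | pathlib.Path) -> None:
    """Write a network to GraphML (undirected)."""
    nx.write_graphml(net, path)


def write_edge_list(net: nx.Graph, path: str | pathlib.Path) -> None:
    """Write a network as a two-column TSV edge list, sorted for determinism."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def curate(net: nx.Graph, keep: str = "largest_component") -> nx.Graph:
    """Curate a network for downstream analysis.

    Policies
    --------
    ``largest_component`` (default)
        Keep only the largest connected component; shortest-path centralities
        are ill-defined across components. Ties broken by smallest node ID.
    ``drop_isolates``
        Remove degree-0 nodes only, the literal "removal of isolated nodes".

    Raises
    ------
    ValueError
        On an unknown policy or an empty result.
    """
    if keep == "largest_component":
        comps = list(nx.connected_components(net))
        if not comps:
            raise ValueError("curate: empty network")
        # tie-break on equal sizes: lexicographically smallest node set, deterministic
        best = min(comps, key=lambda c: (-len(c), tuple(sorted(c))))
        out = net.subgraph(best).copy()
    elif keep == "drop_isolates":
        out = net.copy()
        out.remove_nodes_from(list(nx.isolates(out)))
    else:
        raise ValueError(f"curate: unknown policy {keep!r}")
    if out.number_of_nodes() == 0:
        raise ValueError("curate: result is empty")
    out.name = net.name
    logger.info(
        "curate(%s): %d -> %d nodes, %d -> %d edges", keep,
        net.number_of_nodes(), out.number_of_nodes(),
        net.number_of_edges(), out.number_of_edges(),
    )
    return out


def write_node_table(table: pd.DataFrame, path: str | pathlib.Path) -> None:
    """Write a per-node table as TSV: header row, rows sorted by node ID,
    floats at 6 significant digits.

    Raises
    ------
    ValueError
        If the table is empty.
    """
    if table.empty:
        raise ValueError("write_node_table: empty table")
    if table.columns.duplicated().any():
        raise ValueError("write_node_table: duplicate column names")
    out = table.sort_index()
    out.to_csv(path, sep="\t", index=True, index_label="node", float_format="%.6g")


def read_node_table(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a TSV node table written by :func:`write_node_table`."""
    return pd.read_csv(path, sep="\t", index_col="node")
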