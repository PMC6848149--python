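"""Synthetic networks with planted structure and ground truth.

Every generator returns ``(graph, GroundTruth)``. Together they cover the
statistical features the analysis assumes of a real protein-interaction
network: hierarchical scale-free topology (Ravasz–Barabási model, with its
C(k) ~ k^-1 clustering law), nested modular organization (trees of cliques),
block structure for partition recovery, planted rich-club cores, planted
key-regulator backbones with triangle-free distractor hubs, and
configuration-model graphs with a prescribed degree exponent.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "GroundTruth",
    "ravasz_hierarchical",
    "nested_cliques",
    "planted_partition",
    "planted_rich_club",
    "planted_key_regulator_network",
    "configuration_scale_free",
]


@dataclass
class GroundTruth:
    """What was planted: labels, special node sets and expected exponents."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)
    #: per-level planted community labels: level -> {node -> label}
    labels: dict[int, dict[str, int]] = field(default_factory=dict)
    #: planted high-degree backbone / hub node IDs
    backbone: list[str] = field(default_factory=list)
    #: planted distractor hubs (high degree, triangle-free branch)
    distractors: list[str] = field(default_factory=list)
    #: planted rich-club core node IDs
    rich_club_core: list[str] = field(default_factory=list)
    #: expected power-law exponents by quantity name (signed)
    expected_exponents: dict[str, float] = field(default_factory=dict)
    #: suggested hub-selection threshold covering backbone + distractors
    hub_min_degree: int | None = None
    #: suggested k-range for power-law fitting (well-populated bins)
    fit_k_range: tuple[int, int] | None = None


def ravasz_hierarchical(levels: int) -> tuple[nx.Graph, GroundTruth]:
    """Deterministic Ravasz–Barabási hierarchical scale-free network.

    Starts from a fully connected 5-node module (one center, four
    peripherals). Each iteration makes four replicas of the current module
    and wires every replica's peripheral nodes to the original center, so
    N = 5^levels. The construction yields the hierarchical hallmarks
    C(k) ~ k^-1 and a scale-free-like degree hierarchy; no randomness is
    consumed.
    """
    if not 1 <= levels <= 4:
        raise ValueError("ravasz_hierarchical: levels must be in [1, 4]")
    G = nx.complete_graph(5)
    periph = {1, 2, 3, 4}
    for _ in range(1, levels):
        size = G.number_of_nodes()
        new = nx.Graph()
        new.add_edges_from(G.edges())
        new_periph: set[int] = set()
        for rep in range(1, 5):
            off = rep * size
            new.add_edges_from((u + off, v + off) for u, v in G.edges())
            new_periph |= {p + off for p in periph}
        new.add_edges_from((0, p) for p in new_periph)
        G, periph = new, new_periph

    n = G.number_of_nodes()
    width = len(str(n - 1))
    mapping = {i: f"n{i:0{width}d}" for i in G.nodes}
    H = nx.relabel_nodes(G, mapping)
    H.name = f"ravasz_L{levels}"
    gt = GroundTruth(
        generator="ravasz_hierarchical",
        seed=None,
        params={"levels": levels},
        expected_exponents={"C_k": -1.0},
    )
    # block membership: base-5 prefix of the node index per level
    for lvl in range(1, levels):
        gt.labels[lvl] = {mapping[i]: i // 5 ** (levels - lvl) for i in G.nodes}
    return H, gt


def nested_cliques(
    branching: int = 3,
    depth: int = 2,
    clique_size: int = 5,
    inter_edges: int = 1,
    seed: int = 0,
    escalation: int = 4,
) -> tuple[nx.Graph, GroundTruth]:
    """Balanced tree of communities whose leaves are cliques.

    ``branching^depth`` leaf cliques of ``clique_size`` nodes; at every
    internal level each pair of sibling subtrees is joined by random bridge
    edges. Bridges escalate with depth — a sibling pair whose parent sits at
    tree level L gets ``inter_edges * escalation**L`` bridges — so cohesion
    is strongest inside the deepest groups and weakest between the top-level
    ones, the defining signature of nested modularity. Ground-truth labels
    are recorded at every level.
    """
    if min(branching, depth, clique_size, inter_edges) < 1:
        raise ValueError("nested_cliques: all parameters must be >= 1")
    rng = random.Random(seed)
    G = nx.Graph(name=f"nested_cliques_b{branching}_d{depth}")
    paths = list(itertools.product(range(branching), repeat=depth))
    members: dict[tuple[int, ...], list[str]] = {}
    for path in paths:
        tag = "-".join(map(str, path))
        nodes = [f"c{tag}_n{j}" for j in range(clique_size)]
        members[path] = nodes
        G.add_edges_from(itertools.combinations(nodes, 2))

    def subtree_nodes(prefix: tuple[int, ...]) -> list[str]:
        return [n for p in paths if p[: len(prefix)] == prefix for n in members[p]]

    # bridges between sibling subtrees at every internal node of the tree
    for lvl in range(depth):
        n_bridges = inter_edges * escalation**lvl
        for prefix in itertools.product(range(branching), repeat=lvl):
            groups = [subtree_nodes(prefix + (b,)) for b in range(branching)]
            for a, b in itertools.combinations(range(branching), 2):
                for _ in range(n_bridges):
                    for _try in range(100):
                        u, v = rng.choice(groups[a]), rng.choice(groups[b])
                        if not G.has_edge(u, v):
                            G.add_edge(u, v)
                            break

    gt = GroundTruth(
        generator="nested_cliques",
        seed=seed,
        params={
            "branching": branching,
            "depth": depth,
            "clique_size": clique_size,
            "inter_edges": inter_edges,
            "escalation": escalation,
        },
    )
    for lvl in range(1, depth + 1):
        lab: dict[str, int] = {}
        pfx_ids = {p: i for i, p in enumerate(sorted({q[:lvl] for q in paths}))}
        for path in paths:
            for nod in members[path]:
                lab[nod] = pfx_ids[path[:lvl]]
        gt.labels[lvl] = lab
    return G, gt


def planted_partition(
    sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, GroundTruth]:
    """Planted-partition (stochastic block) graph with known group labels.

    Edges appear with probability ``p_in`` within groups and ``p_out``
    between them; requires 0 ≤ p_out < p_in ≤ 1.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("planted_partition: need 0 <= p_out < p_in <= 1")
    raw = nx.random_partition_graph(sizes, p_in, p_out, seed=seed)
    width = len(str(sum(sizes) - 1))
    mapping = {i: f"n{i:0{width}d}" for i in raw.nodes}
    G = nx.relabel_nodes(nx.Graph(raw.edges()), mapping)
    G.add_nodes_from(mapping.values())
    G.name = "planted_partition"
    labels = {}
    for gid, block in enumerate(raw.graph["partition"]):
        for i in block:
            labels[mapping[i]] = gid
    gt = GroundTruth(
        generator="planted_partition",
        seed=seed,
        params={"sizes": list(sizes), "p_in": p_in, "p_out": p_out},
        labels={1: labels},
    )
    return G, gt


def planted_rich_club(
    n_periphery: int = 300,
    core_size: int = 12,
    p_periphery: float = 0.02,
    seed: int = 0,
    core_periphery_links: int = 4,
) -> tuple[nx.Graph, GroundTruth]:
    """Sparse random periphery plus a clique core — a planted rich club.

    The core is a ``core_size``-clique whose members each also receive
    ``core_periphery_links`` random links into an Erdős–Rényi periphery, so
    core degrees sit at the top of the degree sequence while the clique's
    density far exceeds any degree-preserving null.
    """
    if core_size < 3:
        raise ValueError("planted_rich_club: core_size must be >= 3")
    rng = random.Random(seed)
    peri = nx.gnp_random_graph(n_periphery, p_periphery, seed=seed)
    width = len(str(n_periphery - 1))
    G = nx.relabel_nodes(peri, {i: f"p{i:0{width}d}" for i in peri.nodes})
    core = [f"core{j:02d}" for j in range(core_size)]
    G.add_edges_from(itertools.combinations(core, 2))
    pnodes = sorted(n for n in G.nodes if n.startswith("p"))
    for c in core:
        for tgt in rng.sample(pnodes, core_periphery_links):
            G.add_edge(c, tgt)
    G.name = "planted_rich_club"
    gt = GroundTruth(
        generator="planted_rich_club",
        seed=seed,
        params={
            "n_periphery": n_periphery,
            "core_size": core_size,
            "p_periphery": p_periphery,
            "core_periphery_links": core_periphery_links,
        },
        rich_club_core=core,
    )
    return G, gt


def planted_key_regulator_network(
    n_backbone: int = 3,
    branching: int = 3,
    depth: int = 2,
    seed: int = 0,
    clique_size: int = 6,
    inter_edges: int = 2,
    backbone_extra_edges: int = 24,
    n_distractors: int = 2,
    distractor_leaves: int = 26,
) -> tuple[nx.Graph, GroundTruth]:
    """Nested-clique scaffold with planted backbone hubs and distractor hubs.

    ``n_backbone`` designated nodes (one per distinct top-level branch,
    cycling) sit inside a leaf clique — hence inside a triangle at every
    level — and receive ``backbone_extra_edges`` extra cross-community
    links that push their global degree above the hub threshold.
    ``n_distractors`` decoy hubs of comparable degree are attached as
    star appendages (triangle-free), so their community chain terminates
    in a non-qualifying community. Ground truth records both sets and a
    ``hub_min_degree`` separating hubs from the scaffold bulk.
    """
    if min(n_backbone, branching, depth) < 1:
        raise ValueError("planted_key_regulator_network: parameters must be >= 1")
    rng = random.Random(seed + 101)
    G, gt_nc = nested_cliques(
        branching=branching,
        depth=depth,
        clique_size=clique_size,
        inter_edges=inter_edges,
        seed=seed,
    )
    G.name = "planted_key_regulator"

    # one backbone node per top-level branch (cycling if n_backbone > branching)
    backbone = []
    for i in range(n_backbone):
        branch = i % branching
        path_tag = "-".join([str(branch)] + ["0"] * (depth - 1))
        backbone.append(f"c{path_tag}_n0")
    scaffold = sorted(n for n in G.nodes if n not in backbone)
    for b in backbone:
        targets = [t for t in scaffold if not G.has_edge(b, t)]
        for tgt in rng.sample(targets, min(backbone_extra_edges, len(targets))):
            G.add_edge(b, tgt)

    distractors = []
    for d in range(n_distractors):
        hub = f"distractor{d}"
        distractors.append(hub)
        G.add_edges_from((hub, f"{hub}_leaf{j}") for j in range(distractor_leaves))
        G.add_edge(hub, rng.choice(scaffold))  # single bridge keeps it connected

    base_degree = clique_size - 1 + inter_edges * branching  # scaffold upper bulk
    gt = GroundTruth(
        generator="planted_key_regulator_network",
        seed=seed,
        params={
            "n_backbone": n_backbone,
            "branching": branching,
            "depth": depth,
            "clique_size": clique_size,
            "inter_edges": inter_edges,
            "backbone_extra_edges": backbone_extra_edges,
            "n_distractors": n_distractors,
            "distractor_leaves": distractor_leaves,
        },
        labels=gt_nc.labels,
        backbone=backbone,
        distractors=distractors,
        hub_min_degree=base_degree + 8,
    )
    return G, gt


def configuration_scale_free(
    n: int,
    gamma: float,
    seed: int = 0,
    k_min: int = 2,
    k_max: int | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Configuration-model graph with a truncated power-law degree sequence.

    Degrees are sampled from P(k) ∝ k^-gamma on [k_min, k_max] (default
    k_max = √n) by inverse-CDF of the continuous law, floored. The
    multigraph is simplified (self-loops and parallel edges dropped — a
    small bias at this scale) and the largest component returned.
    ``fit_k_range`` in the ground truth spans the well-populated degree
    bins (expected count ≥ 10), the window where a log-log OLS fit of P(k)
    is meaningful.
    """
    if not 2 <= gamma <= 4:
        raise ValueError("configuration_scale_free: gamma must be in [2, 4]")
    if n < 10:
        raise ValueError("configuration_scale_free: n too small")
    k_max = k_max or max(int(round(np.sqrt(n))), k_min + 2)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    a = 1.0 - gamma
    ks = (k_min**a + u * (k_max**a - k_min**a)) ** (1.0 / a)
    seq = np.floor(ks).astype(int)
    if seq.sum() % 2:
        seq[int(rng.integers(n))] += 1
    multi = nx.configuration_model(seq.tolist(), seed=int(rng.integers(2**31)))
    simple = nx.Graph(multi)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    comp = max(nx.connected_components(simple), key=lambda c: (len(c), sorted(c)[0]))
    sub = simple.subgraph(comp)
    width = len(str(n - 1))
    G = nx.relabel_nodes(sub, {i: f"n{i:0{width}d}" for i in sub.nodes})
    G.name = f"config_sf_g{gamma}"

    # well-populated fit window: expected N_k >= 10 under the sampled law
    counts = np.bincount(seq)
    k_hi = k_min
    for k in range(k_min, k_max + 1):
        if k < len(counts) and counts[k] >= 10:
            k_hi = k
    gt = GroundTruth(
        generator="configuration_scale_free",
        seed=seed,
        params={"n": n, "gamma": gamma, "k_min": k_min, "k_max": k_max},
        expected_exponents={"P_k": -gamma},
        fit_k_range=(k_min, k_hi),
    )
    return G, gt
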