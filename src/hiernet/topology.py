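"""Per-node topological quantities, per-degree spectra and power-law fits.

A hierarchical scale-free network is diagnosed from three degree spectra —
the degree distribution P(k) ~ k^-γ, the mean clustering coefficient
C(k) ~ k^-α with α near 1, and the mean neighbourhood connectivity
C_N(k) ~ k^β (β < 0: disassortative) — together with four centralities
(closeness, betweenness, eigenvector, subgraph) whose spectra rise with k
in such networks. Exponents are estimated by ordinary least squares on
log10–log10 per-degree means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

__all__ = [
    "PowerLawFit",
    "degree",
    "degree_distribution",
    "clustering",
    "neighbourhood_connectivity",
    "closeness",
    "betweenness",
    "eigenvector_centrality",
    "subgraph_centrality",
    "spectrum",
    "fit_power_law",
]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) on log10(k).

    ``exponent`` is the signed slope; ``magnitude`` its absolute value
    (the |γ|, |α|, |β| usually quoted). ``k_range`` is the (k_min, k_max)
    actually used and ``n_excluded`` counts non-positive points dropped
    before taking logs.
    """

    exponent: float
    magnitude: float
    intercept: float
    r_squared: float
    k_range: tuple[float, float]
    n_points: int
    n_excluded: int


def _require_connected(net: nx.Graph, what: str) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError(f"{what}: empty network")
    if not nx.is_connected(net):
        raise ValueError(
            f"{what}: network is disconnected; run graphio.curate(net, "
            "'largest_component') first"
        )


def degree(net: nx.Graph) -> dict[str, int]:
    """Node degree k_i (number of incident edges)."""
    return dict(net.degree())


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """P(k) = N_k / N, the fraction of nodes with degree k."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("degree_distribution: empty network")
    counts: dict[int, int] = {}
    for _, k in net.degree():
        counts[k] = counts.get(k, 0) + 1
    return {k: c / n for k, c in sorted(counts.items())}


def clustering(net: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient C_i = 2 m_i / (k_i (k_i - 1)).

    m_i is the number of edges among the neighbours of i (equivalently the
    triangles through i). Nodes with k_i < 2 get C_i = 0 by convention.
    """
    return {n: float(c) for n, c in nx.clustering(net).items()}


def neighbourhood_connectivity(net: nx.Graph) -> dict[str, float]:
    """Mean degree of a node's neighbours; NaN for isolated nodes.

    Averaged per degree class this is the neighbourhood-connectivity
    spectrum C_N(k) = Σ_q q P(q|k) with the empirical conditional P(q|k).
    """
    out: dict[str, float] = {}
    for node in net.nodes:
        nbrs = list(net[node])
        out[node] = float(np.mean([net.degree(b) for b in nbrs])) if nbrs else math.nan
    return out


def closeness(net: nx.Graph, convention: str = "scaled") -> dict[str, float]:
    """Closeness centrality C_C(i).

    ``convention="scaled"`` uses n / Σ_j d_ij; ``"standard"`` the usual
    (n-1) / Σ_j d_ij. The two differ by the constant factor n/(n-1) and so
    rank nodes identically.

    Raises on disconnected input (geodesics undefined across components).
    """
    _require_connected(net, "closeness")
    if convention not in ("scaled", "standard"):
        raise ValueError(f"closeness: unknown convention {convention!r}")
    std = nx.closeness_centrality(net)
    n = net.number_of_nodes()
    if n == 1:
        return {next(iter(net.nodes)): 0.0}
    factor = n / (n - 1) if convention == "scaled" else 1.0
    return {node: factor * v for node, v in std.items()}


def betweenness(net: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Betweenness centrality.

    Raw: C_b(v) = Σ_{i≠j≠v} d_ij(v)/d_ij over unordered pairs, where
    d_ij(v) counts geodesics through v. Normalized: C_b(v) / M with
    M = (N-1)(N-2)/2 node pairs excluding v.
    """
    _require_connected(net, "betweenness")
    return dict(nx.betweenness_centrality(net, normalized=normalized))


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Principal-eigenvector centrality, normalized to unit maximum.

    Power iteration on A + I: the shift leaves the principal eigenvector of
    A unchanged while guaranteeing convergence on bipartite graphs, whose
    spectrum is symmetric about zero.
    """
    _require_connected(net, "eigenvector_centrality")
    nodes = sorted(net.nodes)
    A = nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float, format="csr")
    x = np.ones(len(nodes)) / math.sqrt(len(nodes))
    for _ in range(max_iter):
        y = A @ x + x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    else:
        resid = float(np.abs((A @ x + x) / np.linalg.norm(A @ x + x) - x).max())
        raise RuntimeError(
            f"eigenvector_centrality: no convergence in {max_iter} iterations "
            f"(residual {resid:.3e})"
        )
    x = np.abs(x)
    x /= x.max()
    return dict(zip(nodes, x.tolist()))


def subgraph_centrality(net: nx.Graph, n_max: int = 20_000) -> dict[str, float]:
    """Subgraph centrality C_S(i) = Σ_j v_j(i)^2 e^{λ_j}.

    The weighted count of closed walks through i (shorter subgraphs weighted
    more), equal to the i-th diagonal entry of e^A. Computed by dense
    eigendecomposition; guarded at ``n_max`` nodes.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("subgraph_centrality: empty network")
    if n > n_max:
        raise ValueError(
            f"subgraph_centrality: {n} nodes exceeds the dense-eigendecomposition "
            f"guard ({n_max}); raise n_max explicitly if you have the memory"
        )
    nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    lam, V = scipy.linalg.eigh(A)
    cs = (V**2) @ np.exp(lam)
    return dict(zip(nodes, cs.tolist()))


def spectrum(net: nx.Graph, vectors: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Per-degree spectra: N_k, P(k) and the mean of each supplied per-node
    quantity over the nodes of each degree class.

    ``vectors`` maps a column name to a node→value map computed on ``net``.
    NaN entries (e.g. neighbourhood connectivity of isolates) are excluded
    from the class means. Returns a DataFrame indexed by k, sorted.
    """
    degs = degree(net)
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("spectrum: empty network")
    ks = sorted(set(degs.values()))
    rows = []
    for k in ks:
        members = [v for v, d in degs.items() if d == k]
        row: dict[str, float] = {"k": k, "N_k": len(members), "P_k": len(members) / n}
        for name, vec in vectors.items():
            vals = np.array([vec[m] for m in members], dtype=float)
            vals = vals[~np.isnan(vals)]
            row[name] = float(vals.mean()) if vals.size else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def fit_power_law(
    spectrum: Mapping[float, float] | pd.Series,
    k_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit y ~ k^s by OLS of log10(y) on log10(k).

    Points with k ≤ 0 or y ≤ 0 are excluded (counted in ``n_excluded``);
    ``k_range`` optionally restricts the fit window. At least 3 usable
    points are required.
    """
    items = list(spectrum.items())
    usable, excluded = [], 0
    for k, y in items:
        if k_range is not None and not (k_range[0] <= k <= k_range[1]):
            continue
        if k <= 0 or not np.isfinite(y) or y <= 0:
            excluded += 1
            continue
        usable.append((float(k), float(y)))
    if len(usable) < 3:
        raise ValueError(
            f"fit_power_law: {len(usable)} usable points (need >= 3); "
            f"{excluded} excluded as non-positive"
        )
    usable.sort()
    logk = np.log10([k for k, _ in usable])
    logy = np.log10([y for _, y in usable])
    res = scipy.stats.linregress(logk, logy)
    return PowerLawFit(
        exponent=float(res.slope),
        magnitude=abs(float(res.slope)),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        k_range=(usable[0][0], usable[-1][0]),
        n_points=len(usable),
        n_excluded=excluded,
    )
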