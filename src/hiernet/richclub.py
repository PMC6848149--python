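"""Rich-club coefficients, degree-preserving null ensembles and regimes.

The rich-club coefficient Φ(k) is the edge density of the subgraph induced
by nodes of degree > k: Φ(k) = 2 E_{>k} / (N_{>k}(N_{>k}−1)). Because high
degrees alone inflate Φ, it is normalized by the mean coefficient of an
ensemble of degree-preserving rewirings (double edge swaps):
Φ_norm(k) = Φ(k) / ⟨Φ_rand(k)⟩, and Φ_norm(k) > 1 signals genuine rich-club
organization at that degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RichClubCurve",
    "rich_club_coefficient",
    "randomize_degree_preserving",
    "normalized_rich_club",
    "rich_club_regimes",
]


@dataclass
class RichClubCurve:
    """Φ(k), null-ensemble statistics and Φ_norm(k) per degree threshold.

    ``table`` is indexed by k with columns n_above, phi, phi_rand_mean,
    phi_rand_sd, phi_norm. Thresholds where fewer than two nodes exceed k,
    or where the null mean is zero, are absent / NaN respectively.
    """

    table: pd.DataFrame
    n_random: int
    swaps_per_edge: int
    seed: int
    strict: bool

    def phi_norm(self) -> pd.Series:
        """Defined Φ_norm values only (NaN rows dropped), indexed by k."""
        return self.table["phi_norm"].dropna()


def rich_club_coefficient(net: nx.Graph, strict: bool = True) -> dict[int, float]:
    """Φ(k) for every degree threshold k where at least two nodes qualify.

    ``strict=True`` (default) uses degree > k (Colizza convention);
    ``strict=False`` uses degree ≥ k. Membership is fixed by degrees in the
    original network, not recomputed inside induced subgraphs.
    """
    degs = dict(net.degree())
    if not degs:
        return {}
    # process thresholds ascending, peeling off nodes as they drop out
    maxdeg = max(degs.values())
    alive = set(net.nodes)
    n_edges = net.number_of_edges()
    adj = {n: set(net[n]) for n in net.nodes}
    by_degree: dict[int, list[str]] = {}
    for n, d in degs.items():
        by_degree.setdefault(d, []).append(n)

    out: dict[int, float] = {}
    ks = range(0, maxdeg) if strict else range(1, maxdeg + 1)
    for k in ks:
        # drop nodes that no longer qualify at threshold k
        drop_deg = k if strict else k - 1
        for node in by_degree.get(drop_deg, []):
            alive.discard(node)
            n_edges -= sum(1 for nbr in adj[node] if nbr in alive)
        n_above = len(alive)
        if n_above >= 2:
            out[k] = 2.0 * n_edges / (n_above * (n_above - 1))
    return out


def randomize_degree_preserving(
    net: nx.Graph, swaps_per_edge: int = 10, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by double edge swaps.

    Attempts ``swaps_per_edge × |E|`` successful swaps; a swap that would
    create a self-loop or duplicate edge is rejected. If the retry budget
    runs out (rigid degree sequences such as complete graphs) the partially
    rewired graph is returned with a logged warning.
    """
    out = net.copy()
    m = out.number_of_edges()
    if swaps_per_edge == 0 or m < 2 or out.number_of_nodes() < 4:
        return out
    nswap = swaps_per_edge * m
    try:
        nx.double_edge_swap(out, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXException as exc:
        logger.warning("randomize_degree_preserving: swap budget exhausted (%s)", exc)
    assert sorted(d for _, d in out.degree()) == sorted(d for _, d in net.degree())
    return out


def normalized_rich_club(
    net: nx.Graph,
    n_random: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    strict: bool = True,
) -> RichClubCurve:
    """Φ(k) normalized against an ensemble of degree-preserving rewirings.

    The ensemble uses seeds ``seed .. seed+n_random−1``. Φ_norm is NaN where
    the null-ensemble mean is zero.
    """
    if n_random < 1:
        raise ValueError("normalized_rich_club: n_random must be >= 1")
    phi = rich_club_coefficient(net, strict=strict)
    ks = sorted(phi)
    ens = np.full((n_random, len(ks)), np.nan)
    for i in range(n_random):
        R = randomize_degree_preserving(net, swaps_per_edge=swaps_per_edge, seed=seed + i)
        phir = rich_club_coefficient(R, strict=strict)
        ens[i] = [phir.get(k, np.nan) for k in ks]

    degs = dict(net.degree())
    rows = []
    for j, k in enumerate(ks):
        col = ens[:, j]
        col = col[~np.isnan(col)]
        mean = float(col.mean()) if col.size else np.nan
        sd = float(col.std()) if col.size else np.nan
        n_above = sum(1 for d in degs.values() if (d > k if strict else d >= k))
        rows.append(
            {
                "k": k,
                "n_above": n_above,
                "phi": phi[k],
                "phi_rand_mean": mean,
                "phi_rand_sd": sd,
                "phi_norm": phi[k] / mean if mean and mean > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    return RichClubCurve(
        table=table, n_random=n_random, swaps_per_edge=swaps_per_edge, seed=seed, strict=strict
    )


def rich_club_regimes(curve: RichClubCurve, min_length: int = 2) -> list[tuple[int, int]]:
    """Maximal contiguous runs of defined degrees with Φ_norm > 1.

    Contiguity is over the sequence of degrees where Φ_norm is defined.
    Runs spanning fewer than ``min_length`` thresholds are dropped. Each
    regime is reported as (k_min, k_max).
    """
    pn = curve.phi_norm()
    regimes: list[tuple[int, int]] = []
    run: list[int] = []
    for k, v in pn.items():
        if v > 1:
            run.append(int(k))
        else:
            if len(run) >= min_length:
                regimes.append((run[0], run[-1]))
            run = []
    if len(run) >= min_length:
        regimes.append((run[0], run[-1]))
    return regimes
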