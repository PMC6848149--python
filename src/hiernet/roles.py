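"""Node-role cartography: within-module degree Z and participation coefficient P.

Given a partition into modules, each node gets a within-module degree
Z-score Z_i = (κ_i − mean κ over its module) / (population sd of κ), and a
participation coefficient P_i = 1 − Σ_s (k_is / k_i)², the spread of its
links across modules. Nodes split into seven roles (Guimerà–Amaral):
non-hubs (Z < 2.5) R1 ultraperipheral / R2 peripheral / R3 non-hub
connector / R4 non-hub kinless, and hubs (Z ≥ 2.5) R5 provincial / R6
connector / R7 kinless, by P thresholds.
"""

from __future__ import annotations

import math
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ROLE_NAMES",
    "within_module_z",
    "participation_coefficient",
    "classify_role",
    "classify_roles",
    "role_table",
]

ROLE_NAMES = {
    "R1": "ultraperipheral",
    "R2": "peripheral",
    "R3": "non-hub connector",
    "R4": "non-hub kinless",
    "R5": "provincial hub",
    "R6": "connector hub",
    "R7": "kinless hub",
}

HUB_Z = 2.5
_NONHUB_P = ((0.05, "R1"), (0.62, "R2"), (0.80, "R3"), (math.inf, "R4"))
_HUB_P = ((0.30, "R5"), (0.75, "R6"), (math.inf, "R7"))


def _check_labels(net: nx.Graph, labels: Mapping[str, int]) -> None:
    missing = set(net.nodes) - set(labels)
    if missing:
        raise ValueError(f"labels missing for {len(missing)} node(s), e.g. {sorted(missing)[:3]}")


def within_module_z(net: nx.Graph, labels: Mapping[str, int]) -> dict[str, float]:
    """Within-module degree Z-score.

    κ_i is the number of links node i has inside its own module; the mean
    and population standard deviation are taken over all nodes of that
    module. Modules where every κ is equal (sd = 0) give Z = 0.
    """
    _check_labels(net, labels)
    modules: dict[int, list[str]] = {}
    for node in net.nodes:
        modules.setdefault(labels[node], []).append(node)
    kappa = {
        node: sum(1 for nbr in net[node] if labels[nbr] == labels[node])
        for node in net.nodes
    }
    z: dict[str, float] = {}
    for members in modules.values():
        ks = np.array([kappa[m] for m in members], dtype=float)
        mu, sd = ks.mean(), ks.std()  # population sd
        for m in members:
            z[m] = float((kappa[m] - mu) / sd) if sd > 0 else 0.0
    return z


def participation_coefficient(net: nx.Graph, labels: Mapping[str, int]) -> dict[str, float]:
    """Participation coefficient P_i = 1 − Σ_s (k_is/k_i)².

    0 when all links stay inside one module; approaches 1 − 1/N_M when the
    links spread evenly over all N_M modules. NaN for isolated nodes.
    """
    _check_labels(net, labels)
    out: dict[str, float] = {}
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            out[node] = math.nan
            continue
        per_mod: dict[int, int] = {}
        for nbr in net[node]:
            per_mod[labels[nbr]] = per_mod.get(labels[nbr], 0) + 1
        out[node] = float(1.0 - sum((c / k) ** 2 for c in per_mod.values()))
    return out


def classify_role(z: float, p: float) -> str:
    """Role class for one (Z, P) pair; boundaries inclusive on the lower class."""
    if math.isnan(p):
        raise ValueError("classify_role: P undefined (isolated node); curate first")
    table = _HUB_P if z >= HUB_Z else _NONHUB_P
    for bound, role in table:
        if p <= bound:
            return role
    raise AssertionError("unreachable")


def classify_roles(z: Mapping[str, float], p: Mapping[str, float]) -> dict[str, str]:
    """Assign the R1–R7 role to every node; both maps must cover the same nodes."""
    if set(z) != set(p):
        diff = set(z) ^ set(p)
        raise ValueError(f"classify_roles: node sets differ by {len(diff)}, e.g. {sorted(diff)[:3]}")
    return {node: classify_role(z[node], p[node]) for node in z}


def role_table(net: nx.Graph, labels: Mapping[str, int], level: int = 1) -> pd.DataFrame:
    """Per-node table: degree, Z, P, role and the partition level used."""
    z = within_module_z(net, labels)
    p = participation_coefficient(net, labels)
    roles = classify_roles(z, p)
    df = pd.DataFrame(
        {
            "degree": {n: d for n, d in net.degree()},
            "Z": z,
            "P": p,
            "role": roles,
        }
    )
    df["partition_level"] = level
    df.index.name = "node"
    return df.sort_index()
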