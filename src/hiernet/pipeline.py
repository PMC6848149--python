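"""End-to-end orchestration: curate → topology → hierarchy → roles →
rich club → hub tracing → key regulators, with a self-describing manifest.

All outputs are plain TSV/JSON under the configured output directory, and
every stage is deterministic given the configured seeds, so a rerun with an
identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import yaml

from hiernet import __version__ as _version
from hiernet import graphio, hierarchy, keyreg, richclub, roles, topology

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run", "summarize", "summarize_dir"]


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run.

    Exactly one of ``hub_min_degree`` / ``hub_top_n`` selects hubs.
    """

    input_path: str
    output_dir: str
    input_format: str = "edgelist"          # edgelist | graphml
    curation: str = "largest_component"     # largest_component | drop_isolates
    louvain_seed: int = 0
    louvain_restarts: int = 1
    resolution: float = 1.0
    max_levels: int = 10
    min_community_size: int = 3
    hub_min_degree: int | None = None
    hub_top_n: int | None = None
    keyreg_mode: str = "global_max_depth"
    role_level: int = 1
    closeness_convention: str = "scaled"
    richclub_n_random: int = 100
    richclub_swaps_per_edge: int = 10
    richclub_seed: int = 0
    richclub_strict: bool = True
    richclub_module_min_size: int = 30
    subgraph_centrality_n_max: int = 20_000

    def __post_init__(self) -> None:
        if (self.hub_min_degree is None) == (self.hub_top_n is None):
            raise ValueError("config: set exactly one of hub_min_degree / hub_top_n")
        if self.input_format not in ("edgelist", "graphml"):
            raise ValueError(f"config: unknown input_format {self.input_format!r}")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# spectrum column -> (exponent symbol, quantity description)
_EXPONENT_TABLE = [
    ("P_k", "gamma", "degree distribution"),
    ("C_k", "alpha", "clustering coefficient"),
    ("CN_k", "beta", "neighbourhood connectivity"),
    ("CC_k", "epsilon", "closeness centrality"),
    ("CB_k", "eta", "betweenness centrality"),
    ("CE_k", "delta", "eigenvector centrality"),
    ("CS_k", "zeta", "subgraph centrality"),
]


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory bundle and writes
    every table/JSON plus ``manifest.json`` into ``config.output_dir``."""
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config, "output_dir": str(outdir)}
    manifest: dict = {"hiernet_version": _version, "config": config.to_dict(), "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # --- graphio -------------------------------------------------------
    try:
        stage("graphio")
        reader = graphio.read_edge_list if config.input_format == "edgelist" else graphio.read_graphml
        raw = reader(config.input_path)
        net = graphio.curate(raw, keep=config.curation)
        manifest["stages"]["graphio"] = {
            "raw_nodes": raw.number_of_nodes(),
            "raw_edges": raw.number_of_edges(),
            "curated_nodes": net.number_of_nodes(),
            "curated_edges": net.number_of_edges(),
        }
        bundle["network"] = net
    except Exception as exc:
        raise PipelineStageError("graphio", exc) from exc

    # --- topology ------------------------------------------------------
    try:
        stage("topology")
        vectors = {
            "C_k": topology.clustering(net),
            "CN_k": topology.neighbourhood_connectivity(net),
            "CC_k": topology.closeness(net, convention=config.closeness_convention),
            "CB_k": topology.betweenness(net, normalized=True),
            "CE_k": topology.eigenvector_centrality(net),
            "CS_k": topology.subgraph_centrality(net, n_max=config.subgraph_centrality_n_max),
        }
        node_table = pd.DataFrame(vectors)
        node_table.insert(0, "degree", pd.Series(topology.degree(net)))
        node_table.index.name = "node"
        spec = topology.spectrum(net, vectors)
        fits = {}
        fit_rows = []
        for col, symbol, desc in _EXPONENT_TABLE:
            try:
                f = topology.fit_power_law(spec[col] if col != "P_k" else spec["P_k"])
            except ValueError:
                continue
            fits[symbol] = f
            fit_rows.append(
                {
                    "quantity": col,
                    "symbol": symbol,
                    "description": desc,
                    "exponent": f.exponent,
                    "magnitude": f.magnitude,
                    "r2": f.r_squared,
                    "k_min": f.k_range[0],
                    "k_max": f.k_range[1],
                    "n_points": f.n_points,
                }
            )
        fits_df = pd.DataFrame(fit_rows).set_index("quantity")
        graphio.write_node_table(node_table, outdir / "node_table.tsv")
        spec.to_csv(outdir / "spectrum.tsv", sep="\t", float_format="%.6g")
        fits_df.to_csv(outdir / "fits.tsv", sep="\t", float_format="%.6g")
        bundle.update(node_table=node_table, spectrum=spec, fits=fits, fits_table=fits_df)
        manifest["stages"]["topology"] = {"n_degree_bins": int(len(spec))}
    except Exception as exc:
        raise PipelineStageError("topology", exc) from exc

    # --- hierarchy -----------------------------------------------------
    try:
        stage("hierarchy")
        tree = hierarchy.build_hierarchy(
            net,
            seed=config.louvain_seed,
            max_levels=config.max_levels,
            min_size=config.min_community_size,
            resolution=config.resolution,
            restarts=config.louvain_restarts,
        )
        levels = hierarchy.level_summary(tree)
        tree.to_json(outdir / "hierarchy.json")
        tree.membership_table().to_csv(outdir / "membership.tsv", sep="\t")
        levels.to_csv(outdir / "level_summary.tsv", sep="\t", float_format="%.6g")
        bundle.update(tree=tree, level_summary=levels)
        manifest["stages"]["hierarchy"] = {
            "max_depth": tree.max_depth,
            "n_communities_total": sum(1 for c in tree.walk()) - 1,
            "n_qualifying_total": sum(1 for c in tree.walk() if c.level > 0 and c.qualifies),
        }
    except Exception as exc:
        raise PipelineStageError("hierarchy", exc) from exc

    # --- roles ---------------------------------------------------------
    try:
        stage("roles")
        lvl = min(config.role_level, max(tree.max_depth, 1))
        comms = tree.communities_at(lvl)
        labels = {n: i for i, c in enumerate(comms) for n in c.nodes}
        if not labels:  # unsplit network: single module
            labels = {n: 0 for n in net.nodes}
        role_df = roles.role_table(net, labels, level=lvl)
        graphio.write_node_table(role_df, outdir / "roles.tsv")
        bundle["roles"] = role_df
        census = role_df["role"].value_counts().to_dict()
        manifest["stages"]["roles"] = {"level": lvl, "census": {r: int(census.get(r, 0)) for r in roles.ROLE_NAMES}}
    except Exception as exc:
        raise PipelineStageError("roles", exc) from exc

    # --- rich club -----------------------------------------------------
    try:
        stage("richclub")
        curve = richclub.normalized_rich_club(
            net,
            n_random=config.richclub_n_random,
            swaps_per_edge=config.richclub_swaps_per_edge,
            seed=config.richclub_seed,
            strict=config.richclub_strict,
        )
        regimes = richclub.rich_club_regimes(curve)
        curve.table.to_csv(outdir / "richclub.tsv", sep="\t", float_format="%.6g")
        module_curves: dict[str, richclub.RichClubCurve] = {}
        module_regimes: dict[str, list] = {}
        for comm in tree.communities_at(1):
            if len(comm.nodes) < config.richclub_module_min_size:
                continue
            sub = net.subgraph(comm.nodes)
            mc = richclub.normalized_rich_club(
                sub,
                n_random=config.richclub_n_random,
                swaps_per_edge=config.richclub_swaps_per_edge,
                seed=config.richclub_seed,
                strict=config.richclub_strict,
            )
            module_curves[comm.id] = mc
            module_regimes[comm.id] = richclub.rich_club_regimes(mc)
            mc.table.to_csv(outdir / f"richclub_{comm.id}.tsv", sep="\t", float_format="%.6g")
        bundle.update(richclub=curve, richclub_regimes=regimes,
                      richclub_modules=module_curves, richclub_module_regimes=module_regimes)
        manifest["stages"]["richclub"] = {
            "regimes": [list(r) for r in regimes],
            "module_regimes": {k: [list(r) for r in v] for k, v in module_regimes.items()},
        }
    except Exception as exc:
        raise PipelineStageError("richclub", exc) from exc

    # --- key regulators ------------------------------------------------
    try:
        stage("keyreg")
        hubs = keyreg.select_hubs(net, min_degree=config.hub_min_degree, top_n=config.hub_top_n)
        traces = keyreg.trace_hubs(tree, hubs)
        kr = keyreg.identify_key_regulators(traces, mode=config.keyreg_mode)
        partners = keyreg.motif_partners(tree, kr)
        kr_table = keyreg.key_regulator_table(traces, kr)
        kr_table.to_csv(outdir / "keyregulators.tsv", sep="\t")
        keyreg.write_motif_partners(partners, outdir / "motif_partners.json")
        bundle.update(hubs=hubs, traces=traces, key_regulators=kr, motif_partners=partners,
                      keyreg_table=kr_table)
        manifest["stages"]["keyreg"] = {
            "n_hubs": len(hubs),
            "n_key_regulators": len(kr),
            "key_regulators": kr,
        }
    except Exception as exc:
        raise PipelineStageError("keyreg", exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle


_REQUIRED_BUNDLE = ["network", "level_summary", "fits_table", "roles", "richclub", "key_regulators"]


def summarize(bundle: dict) -> str:
    """Human-readable run summary: level counts and mean Q, exponent table,
    role census, rich-club regimes, key regulators."""
    missing = [k for k in _REQUIRED_BUNDLE if k not in bundle]
    if missing:
        raise ValueError(f"summarize: bundle incomplete, missing stages for {missing}")
    net: nx.Graph = bundle["network"]
    lines = [
        f"hiernet {_version} run summary",
        f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges",
        "",
        "hierarchy levels (communities, qualifying, mean Q):",
    ]
    for level, row in bundle["level_summary"].iterrows():
        lines.append(
            f"  level {level}: {int(row.n_communities)} communities, "
            f"{int(row.n_qualifying)} qualifying, mean Q = {row.mean_Q:.4f}"
        )
    lines.append("")
    lines.append("power-law exponents (signed):")
    for _, row in bundle["fits_table"].iterrows():
        lines.append(
            f"  {row['symbol']:>8s} ({row['description']}): {row['exponent']:+.3f}  "
            f"r2 = {row['r2']:.3f}"
        )
    census = bundle["roles"]["role"].value_counts()
    lines.append("")
    lines.append("role census: " + ", ".join(
        f"{r}={int(census.get(r, 0))}" for r in roles.ROLE_NAMES
    ) + f"  (total {int(census.sum())})")
    regimes = bundle.get("richclub_regimes", [])
    lines.append("rich-club regimes (phi_norm > 1): " + (
        ", ".join(f"{a} <= k <= {b}" for a, b in regimes) if regimes else "none"
    ))
    for cid, regs in bundle.get("richclub_module_regimes", {}).items():
        if regs:
            lines.append(f"  module {cid}: " + ", ".join(f"{a} <= k <= {b}" for a, b in regs))
    kr = bundle["key_regulators"]
    lines.append("")
    lines.append(f"key regulators ({len(kr)}): " + (", ".join(kr) if kr else "none"))
    return "\n".join(lines) + "\n"


def summarize_dir(outdir: str | pathlib.Path) -> str:
    """Summarize a completed run directory from its written artifacts."""
    outdir = pathlib.Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"summarize_dir: no manifest.json in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    levels = pd.read_csv(outdir / "level_summary.tsv", sep="\t", index_col="level")
    fits = pd.read_csv(outdir / "fits.tsv", sep="\t")
    role_df = graphio.read_node_table(outdir / "roles.tsv")
    g = manifest["stages"]["graphio"]
    lines = [
        f"hiernet {manifest['hiernet_version']} run summary",
        f"network: {g['curated_nodes']} nodes, {g['curated_edges']} edges",
        "",
        "hierarchy levels (communities, qualifying, mean Q):",
    ]
    for level, row in levels.iterrows():
        lines.append(
            f"  level {level}: {int(row.n_communities)} communities, "
            f"{int(row.n_qualifying)} qualifying, mean Q = {row.mean_Q:.4f}"
        )
    lines.append("")
    lines.append("power-law exponents (signed):")
    for _, row in fits.iterrows():
        lines.append(
            f"  {row['symbol']:>8s} ({row['description']}): {row['exponent']:+.3f}  "
            f"r2 = {row['r2']:.3f}"
        )
    census = role_df["role"].value_counts()
    lines.append("")
    lines.append("role census: " + ", ".join(
        f"{r}={int(census.get(r, 0))}" for r in roles.ROLE_NAMES
    ) + f"  (total {int(census.sum())})")
    regs = manifest["stages"]["richclub"]["regimes"]
    lines.append("rich-club regimes (phi_norm > 1): " + (
        ", ".join(f"{a} <= k <= {b}" for a, b in regs) if regs else "none"
    ))
    kr = manifest["stages"]["keyreg"]["key_regulators"]
    lines.append("")
    lines.append(f"key regulators ({len(kr)}): " + (", ".join(kr) if kr else "none"))
    return "\n".join(lines) + "\n"
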