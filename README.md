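# hiernet

Hierarchical network analysis for identifying **key regulator** genes in
undirected protein–protein interaction (PPI) networks — or any network with
nested modular organization.

## The problem

Disease-gene studies often reduce a PPI network to its highest-degree hubs,
or to overrepresented motifs, or to modules — each in isolation. `hiernet`
implements a pipeline that ties the three together: a network is decomposed
into a multi-level hierarchy of communities by recursive modularity
maximization, down to the level of the triangle motif *G*(3,3) (three nodes,
three edges — the minimal cohesive unit); high-degree hubs are then traced
through their chain of nested communities, and the hubs that persist inside
triangle-containing communities at **every** level of the hierarchy are
reported as key regulators, the putative backbone of the network.

Around that core the package computes the standard characterization of
hierarchical scale-free topology and modular structure:

- **Degree spectra and exponents** — P(k) ~ k^−γ, mean clustering
  C(k) ~ k^−α (α ≈ 1 signals hierarchical organization), neighbourhood
  connectivity C_N(k) ~ k^β (β < 0: disassortative), fit by OLS on
  log₁₀–log₁₀ per-degree means.
- **Centralities** — closeness C_C, betweenness C_B, eigenvector C_E and
  subgraph centrality C_S(i) = Σ_j v_j(i)² e^{λ_j} (diagonal of e^A), with
  their spectra against degree.
- **Community hierarchy** — seeded Louvain modularity (Q) maximization,
  applied recursively to each community's induced subgraph until no
  triangle remains or no further split is possible; per-level community
  counts and mean Q.
- **Node-role cartography** — within-module degree Z_i and participation
  coefficient P_i = 1 − Σ_s (k_is/k_i)², with the seven Guimerà–Amaral
  roles R1–R7 (hubs at Z ≥ 2.5; ultraperipheral → kinless by P).
- **Rich clubs** — Φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1)) normalized against
  degree-preserving double-edge-swap ensembles; contiguous degree ranges
  with Φ_norm > 1 are reported as rich-club regimes.
- **Synthetic generators** — Ravasz–Barabási hierarchical networks, nested
  clique trees, planted partitions, planted rich-club cores, planted
  key-regulator backbones with triangle-free distractor hubs, and
  configuration-model graphs with prescribed degree exponent — each with
  ground-truth labels, so the whole pipeline is testable end to end.

## Worked example

Generate a network with three planted backbone hubs and two decoy hubs,
run the pipeline, and summarize:

```sh
hiernet synth planted_key_regulator --seed 3 --out fixture
cat > cfg.yaml <<EOF
input_path: fixture.tsv
output_dir: out
hub_min_degree: 19
richclub_n_random: 100
EOF
hiernet run --config cfg.yaml
```

The summary printed at the end of the run (also available later via
`hiernet summarize out`):

```
hiernet 0.1.0 run summary
network: 108 nodes, 339 edges

hierarchy levels (communities, qualifying, mean Q):
  level 1: 5 communities, 3 qualifying, mean Q = 0.5647
  level 2: 9 communities, 9 qualifying, mean Q = 0.2692

power-law exponents (signed):
     gamma (degree distribution): -1.049  r2 = 0.695
     alpha (clustering coefficient): -1.023  r2 = 0.992
      beta (neighbourhood connectivity): -0.448  r2 = 0.388
   epsilon (closeness centrality): +0.129  r2 = 0.841
       eta (betweenness centrality): +2.829  r2 = 0.600
     delta (eigenvector centrality): +1.244  r2 = 0.535
      zeta (subgraph centrality): +1.911  r2 = 0.569

role census: R1=58, R2=45, R3=1, R4=0, R5=2, R6=2, R7=0  (total 108)
rich-club regimes (phi_norm > 1): none

key regulators (3): c2-0_n0, c0-0_n0, c1-0_n0
```

Reading it: the network decomposes into two hierarchical levels; the two
non-qualifying level-1 communities are the triangle-free decoy appendages.
Mean modularity decays toward the motif level. α ≈ 1 and β < 0 are the
hierarchical, disassortative signature; the centrality exponents are
positive (centralities grow with degree). The three planted backbone hubs —
and only they — are recovered as key regulators: their community chains
reach the deepest level through triangle-containing communities, while the
decoys' chains terminate in triangle-free communities.

All outputs are plain TSV/JSON in `out/` (node table, spectra, exponent
fits, hierarchy tree, membership per level, roles, rich-club curves,
key-regulator report, and a `manifest.json` recording every parameter and
seed). Runs are byte-for-byte reproducible given the same config.

The library can be used directly as well — see `hiernet.topology`,
`hiernet.hierarchy`, `hiernet.roles`, `hiernet.richclub`, `hiernet.keyreg`
and `hiernet.synthdata`; `docs/methods.md` describes the model choices.

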