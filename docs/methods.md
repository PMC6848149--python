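# Methods

This note records the models, conventions and numerical choices behind
`hiernet`, and what the synthetic benchmarks do and do not establish.

## Network model and curation

The unit of analysis is an undirected simple graph with opaque string node
identifiers (gene symbols in the PPI use case, never normalized or mapped).
Self-loops and duplicate edges are dropped at ingestion with logged counts.
Two curation policies exist: `largest_component` (default) and
`drop_isolates`. The default is the stricter one because closeness and
betweenness are defined through geodesics and are meaningless across
components; `drop_isolates` is offered for workflows that only need
component-safe quantities. Both are idempotent.

## Topology

**Degree spectra.** For each observed degree k the package records
N_k, P(k) = N_k/N, and the mean over the degree class of any per-node
quantity (clustering, neighbourhood connectivity, centralities). The
neighbourhood-connectivity spectrum C_N(k) = Σ_q q·P(q|k) is estimated with
the empirical conditional P(q|k), i.e. the mean neighbour degree per node
averaged within each degree class. Local clustering uses
C_i = 2m_i/(k_i(k_i−1)) with C_i = 0 for k_i < 2; those zeros are excluded
automatically from log-log fits (log of zero is undefined), and the count
of excluded points is reported with each fit.

**Centralities.**

- Closeness supports two conventions: `scaled` C_C(i) = n/Σ_j d_ij and
  `standard` (n−1)/Σ_j d_ij. They differ by the constant n/(n−1), so node
  rankings are identical; the choice only matters when comparing absolute
  values across networks of different size.
- Betweenness is the geodesic-fraction sum over unordered pairs; the
  normalized variant divides by M = (N−1)(N−2)/2, the number of pairs
  excluding the focal node, so values lie in [0, 1].
- Eigenvector centrality is computed by power iteration on A + I
  (tolerance 1e-10 on the max-norm update, cap 10,000 iterations,
  normalized to unit maximum). The identity shift leaves the principal
  eigenvector unchanged but guarantees convergence on bipartite graphs
  (stars, trees), whose adjacency spectrum is symmetric about zero and
  defeats bare power iteration.
- Subgraph centrality is the diagonal of the matrix exponential,
  C_S(i) = Σ_j v_j(i)² e^{λ_j}, via dense symmetric eigendecomposition.
  A guard (default 20,000 nodes) protects against accidental O(N³)/O(N²)
  blowups; raise it explicitly for larger networks with enough memory.

**Power-law fits.** Exponents are estimated by ordinary least squares of
log₁₀(y) on log₁₀(k) over per-degree means, reporting the signed slope, its
magnitude, r² and the k-window used. OLS on log-log spectra is the
appropriate estimator here because the fitted quantities are per-degree
*means* (C(k), C_N(k), centrality spectra), not raw tail probabilities;
for P(k) a maximum-likelihood (Clauset-style) estimator is the stronger
alternative but is deliberately not the default, since all quantities are
then treated by one transparent procedure. Degree bins in the sparse tail
carry one or two nodes and flatten an OLS slope; fits accept an explicit
`k_range`, and the configuration-model generator reports the well-populated
window (expected bin count ≥ 10) alongside its ground truth for exactly
this purpose.

## Community hierarchy

Level 1 is a seeded Louvain partition of the curated network; level ℓ+1 is
obtained by re-running Louvain on the induced subgraph of each level-ℓ
community, ignoring edges that leave the community (sub-communities are
built *from* their community, as a nested decomposition requires). A
community is re-clustered only while it can host the triangle motif
G(3,3): communities with no triangle, fewer than `min_size` (default 3)
nodes, or for which Louvain returns a single community become terminal
leaves. A depth cap (`max_levels`, default 10) bounds the recursion; the
deepest level is whatever the data produce, not a fixed constant. Level 1
always exists — an unsplittable network yields one level-1 leaf — so every
node has a community chain of length ≥ 1.

Louvain is stochastic; the implementation fixes the seed (and optionally
takes the best modularity of R restarts, default 1), and internally
relabels nodes to sorted integers so results cannot depend on string
hashing. Identical seed and graph give an identical tree, and the full
pipeline is byte-reproducible.

Per level the summary reports community counts, how many qualify (contain
a triangle), and the mean modularity of the partitions that produced that
level. On nested benchmarks this mean Q decreases monotonically with depth
toward zero at the motif level, the signature of hierarchy exhaustion.

One property of flat modularity maximization worth knowing: on deeply
nested benchmarks (three or more planted levels) the first Louvain cut can
land on an intermediate planted level rather than the coarsest one — the
well-known resolution limit. The recursion still unfolds the levels below;
only the alignment between "detected level 1" and "coarsest planted level"
is affected, and on two-level benchmarks the top level is recovered
exactly.

## Node roles

Within-module degree Z_i standardizes the intra-module link count κ_i by
the module's mean and *population* standard deviation (the Guimerà–Amaral
convention); modules whose members all have equal κ give Z = 0. The
participation coefficient P_i = 1 − Σ_s (k_is/k_i)² is 0 when all links
concentrate in a single module and approaches 1 − 1/N_M for even spread.
Roles: non-hubs (Z < 2.5) split at P ≤ 0.05 / ≤ 0.62 / ≤ 0.80 / > 0.80
into R1–R4; hubs (Z ≥ 2.5) split at P ≤ 0.30 / ≤ 0.75 / > 0.75 into
R5–R7. Boundary values belong to the lower class. Roles are computed
against the level-1 partition by default; any level of the hierarchy can
be selected.

## Rich clubs

Φ(k) is the edge density among nodes of degree strictly greater than k
(a `strict=False` flag switches to ≥). Club membership is fixed by degrees
in the original network and not recomputed inside induced subgraphs. The
null model is double-edge-swap rewiring (default 10 accepted swaps per
edge, 100 rewired replicas), which preserves the degree sequence exactly —
asserted on every call; rigid sequences (e.g. complete graphs) that
exhaust the retry budget return the current state with a warning, which is
correct for them since the degree sequence admits (essentially) one graph.
Φ_norm(k) = Φ(k)/⟨Φ_rand(k)⟩; thresholds with fewer than two club members,
or a zero null mean, are left undefined. Regimes are maximal contiguous
runs of defined thresholds with Φ_norm > 1, dropping runs shorter than 2.

A caveat that matters when reading Φ_norm curves: at thresholds where only
a few dozen nodes remain, the observed Φ is a single draw whose relative
spread against its own rewiring null reaches 15–25%, so isolated
excursions of Φ_norm outside ±0.15 at the tail are expected noise, in
either direction. Sustained, monotone elevation across a degree range —
what the regime extractor looks for — is the meaningful signal; a planted
clique core produces Φ_norm of 5–10, an order of magnitude above this
noise floor.

## Hub tracing and key regulators

Hubs are selected by absolute degree threshold or top-n (ties broken by
node ID); the threshold is a free parameter because any absolute value is
specific to one network's degree scale. Each hub's chain of nested
communities is read off the hierarchy. The default key-regulator criterion
is: the chain reaches the maximum depth attained anywhere in the tree, and
every community on it contains a triangle. A laxer `branch_max_depth` mode
accepts hubs whose chain is fully qualifying as deep as its own branch
goes. Raising the degree threshold can only shrink the key-regulator set.
For each key regulator the members of (and edges within) its terminal
community are reported as its motif-level partners.

## Synthetic benchmarks

The generators produce the structures the analysis assumes, with ground
truth, at desk scale (tens to thousands of nodes):

- `ravasz_hierarchical` — the deterministic 5-node-module replica
  construction; at 3 levels (125 nodes) its clustering spectrum fits
  C(k) ~ k^−1.14, the α ≈ 1 hierarchical law.
- `nested_cliques` — a balanced tree of clique leaves with random sibling
  bridges that multiply by `escalation` (default 4) per level, so cohesion
  increases with depth; used for hierarchy recovery (two-level default:
  45 nodes, recovered at NMI 1.0).
- `planted_partition` — standard block model for partition and role tests.
- `planted_rich_club` — Erdős–Rényi periphery (default 300 nodes,
  p = 0.02) plus a 12-clique core with 4 periphery links per core node,
  placing core degrees at the top of the sequence.
- `planted_key_regulator_network` — nested-clique scaffold, one backbone
  node per top branch boosted by cross-community edges (degree ≈ 30
  against a scaffold bulk of ≈ 11), plus star-shaped triangle-free
  distractor hubs of comparable degree.
- `configuration_scale_free` — truncated power-law degree sequence
  (k ∈ [2, √n]) wired by the configuration model and simplified; dropping
  loops and multi-edges slightly thins the highest degrees, a bias that is
  negligible below the structural cutoff at this scale.

All stochastic generators are reproducible from their seed; the Ravasz
construction consumes no randomness.

What these benchmarks show: every stage recovers planted structure of the
kind it targets, at the stated sizes, with correctly calibrated nulls.
What they do not show: performance on real interactome data, whose degree
correlations, annotation biases and measurement noise none of the
generators emulate; absolute thresholds (hub degree, module-size floors)
always need re-choosing per dataset.

## Problem sizes and defaults

Benchmarks and the reproduction script run at the sizes above (45–5,000
nodes), chosen so that planted effects are comfortably above sampling noise
while everything recomputes in seconds on a laptop. Key defaults: Louvain
seed 0, resolution 1.0, 1 restart; recursion floor 3 nodes, cap 10 levels;
rich-club ensemble 100 replicas × 10 swaps/edge; role partition level 1;
per-module rich-club curves for level-1 modules of ≥ 30 nodes (smaller
modules give degenerate curves). Every default is recorded in each run's
`manifest.json`.
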