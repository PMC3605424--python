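# Methods

## Problem and model

Given an undirected simple graph *G(V, E)* of protein–protein interactions,
an expression matrix giving each protein a vector of *s* expression levels,
and a reference set of essential proteins, the package ranks proteins by six
centrality measures and evaluates the rankings against the reference set.

The central measure is CoEWC:

    CoEWC(u) = Σ_{v ∈ N(u)} PCC(u, v) · CC(v)

* **PCC(u, v)** — sample Pearson correlation of the two expression profiles.
  The population-vs-sample normalisation (s vs s−1) cancels in the ratio, so
  the centred-dot-product form is computed directly and clamped to [−1, 1]
  against floating-point excursions.
* **CC(v)** — Watts–Strogatz local clustering coefficient,
  2·e(N(v)) / (k_v(k_v−1)), computed via `networkx.clustering`.

The modelling assumptions the measure encodes: essential proteins
participate in densely connected, co-expressed modules; party hubs and date
hubs are both essential but differ in their *own* clustering, while their
*neighbours* are similarly clustered in both cases; hubs whose partners are
mutually disconnected singletons are typically non-essential artefacts of
interaction screens.

## Conventions for degenerate inputs

These conventions keep every protein scoreable and are load-bearing for real
interactome data, where coverage is always partial:

* A protein absent from the expression matrix maps to the all-zero profile;
  any profile with zero standard deviation has PCC 0 with every partner
  (Pearson correlation is undefined there; 0 is the only value that lets
  such proteins flow through scoring).
* Per-cell missing values (`NA`) are rejected at parse time — only
  whole-protein absence is imputed.
* CC(u) = 0 for k_u ≤ 1; ECC(u, v) = 0 when min(k_u−1, k_v−1) = 0. No metric
  ever raises on a degenerate node or edge.
* Isolated proteins get score 0 under every measure (empty sums).
* Self-interactions and repeated interactions are filtered on load; a pure
  self-interaction line still registers its protein as an isolated node.

## ECC variant

The edge clustering coefficient is

    ECC(u, v) = |N(u) ∩ N(v)| / min(k_u − 1, k_v − 1)

the realised fraction of possible triangles through the edge, so every edge
inside a clique saturates at 1 regardless of clique size — the property that
makes SoECC of a clique node collapse to its degree. The Radicchi-style
variant with numerator |N(u)∩N(v)|+1 is available (`ecc_variant:
plus-one`); it exceeds 1 on clique edges and is not the default.

## Ranking and evaluation

* Rankings sort by score descending, ties broken by ascending protein ID.
  Reproducible top-k sets require a total order; lexicographic tie-breaking
  is arbitrary but deterministic.
* Scores are computed on the full loaded network, including small components
  and isolated nodes; restriction to the largest connected component is a
  CLI flag, default off.
* The jackknife curve records, at each rank r = 1..max_rank, the number of
  reference essential proteins among the top r. Its AUC is the trapezoidal
  area over the rank axis (`numpy.trapezoid` on the cumulative counts).
  AUC values are therefore comparable only at a fixed max_rank; the package
  reports the rank range alongside every AUC it writes.
* Random baselines are jackknife curves of uniform permutations of the node
  list, drawn from `numpy.random.default_rng(seed)`; their mean cumulative
  count at rank r has hypergeometric expectation r·|ess|/|V|, which the test
  suite verifies at 200 shuffles.
* Proteins not in the reference list are non-essential by definition.

## Synthetic planted-hub benchmark

The generator emulates the modular structure the hub taxonomy presumes:

* **Background**: disjoint cliques (default twelve 10-cliques).
* **Party hubs** (default 2): each adopts one clique and connects to all its
  members, so hub and neighbours sit in one dense module (CC(hub) = 1).
* **Date hubs** (default 2): each connects to one *anchor* member in each of
  ten cliques that host no party hub (CC(hub) = 0, every neighbour
  well-clustered).
* **Noisy hubs** (default 2): star centres over fresh, pairwise non-adjacent
  leaves — the degree-matched negative control (every neighbour CC = 0).

All hub degrees are 10 under the defaults, so degree centrality cannot
separate the classes and any separation is attributable to the
expression/clustering signal.

Expression uses a shared-latent-factor model over s = 36 samples (the length
of a typical yeast metabolic-cycle time course): each party/date hub carries
a latent i.i.d. N(0,1) signal z; each of its neighbours gets
α·z + σ·η with independent N(0,1) noise η, σ = `noise_sd` = 0.2 and
α = σρ/√(1−ρ²) so the population hub–neighbour correlation equals
ρ = `target_pcc_signal` = 0.8, a strong but realistic co-expression level
for complex co-members. All other proteins get independent N(0,1) noise.
A neighbour claimed by two hubs keeps the first (party before date)
assignment; under the defaults the attachment scheme makes claims disjoint.
Party and date hubs are labelled essential with probability 1 and noisy hubs
non-essential, making the planted ground truth binary.

What the generator does **not** emulate: overlapping complexes, scale-free
degree tails, correlated false positives, periodic (rather than stationary
Gaussian) expression dynamics, or partially essential modules. Passing the
planted-hub tests demonstrates that the measures respond to the intended
structural/co-expression signal, not that real-interactome precision
figures will be reproduced.

`perturb` adds/removes uniformly chosen edge fractions (floor semantics) to
emulate false positives/negatives of interaction screens, preserving the
node set and simple-graph invariants.

## Problem sizes and determinism

The default benchmark network has 146 proteins; test batteries use up to
100 random graphs of ≤ 50 nodes, 20 generator seeds, and 200 baseline
shuffles — sizes at which brute-force oracles (exhaustive triangle and
common-neighbour enumeration) remain exact and fast. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; generation,
scoring and evaluation are deterministic given the seed, and the CLI writes
run metadata capturing every parameter.

## Known limitations

* CoEWC inherits expression-platform noise: profiles with near-zero variance
  produce unstable correlations (they are exactly 0 only in the
  strictly-constant case).
* Within a party module, ordinary members can score nearly as high as the
  hub itself (they share the module's co-expression and clustering), so
  CoEWC separates hub *classes* rather than hubs from their own module.
* AUCs are rank-range dependent; comparing values across different
  max_rank settings is meaningless.
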