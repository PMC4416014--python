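# Methods

## The model

A 2-class heterogeneous network (2-HN) is an undirected weighted graph
whose nodes carry one of two classes (A, B) and whose edges therefore
fall into three channels: A–A, A–B and B–B. The three channels are
assumed to originate from different measurement processes (structural
similarity, curated interaction databases, …), so their densities and
weight scales are not comparable; any quality function that pools them
implicitly weights one source against another by an arbitrary factor.

Mixed modularity scores a partition per channel and per module:

    mQ = (1/3) Σ_c { [l_Ac/m_A − (d_Ac/2m_A)²]
                   + [l_Πc/m_Π − k_Πc·d_Πc/m_Π²]
                   + [l_Bc/m_B − (d_Bc/2m_B)²] }

i.e. the arithmetic mean of Newman–Girvan modularity on the two
within-class subnetworks and Barber bipartite modularity on the
cross-class subnetwork, all evaluated on one shared partition. Key
consequences:

- **Channel-scale invariance.** Multiplying all weights of one channel
  by a positive constant changes neither mQ nor (for a fixed seed) the
  detected partition. This is the design goal: integration artifacts in
  a 2-HN cannot tilt the optimization.
- **Single-class modules** need no special casing: a module with no B
  nodes simply has zero bipartite and B-channel terms and competes
  through its A channel only.
- **Empty channels** contribute 0 for every module (the limit of the
  term as the channel weight goes to zero with no internal edges).
  A network with no edges at all has no defined mQ.
- The all-in-one partition scores exactly 0; the implementation
  accumulates module degree sums edge-wise (adding 2w in one step for
  an internal edge) so this identity holds to the last bit, not merely
  to rounding error.
- Degrees are computed strictly per channel: an A–A edge never enters a
  node's bipartite degree. The bipartite degrees d_Πc are taken in the
  full bipartite subnetwork G_Π, consistent with Barber modularity.

## The optimizer

MixMod is a Louvain-style two-phase search:

1. **Local moving.** Nodes are swept in seeded random order (shuffled
   anew each sweep; `node_order="input"` disables shuffling). Each node
   is offered every module adjacent to it through any channel and takes
   the first move with maximal strictly positive mQ gain; gains are
   computed incrementally in O(degree) from channel-separated module
   sums. Sweeps repeat until one changes nothing, which makes the
   result a genuine local optimum of single-node moves.
2. **Aggregation.** Each module collapses into up to two class-pure
   supernodes (its A-side and B-side submodules). Internal submodule
   weight becomes a self-loop; a self-loop of weight w counts w toward
   its channel total and 2w toward its node's degree. Keeping
   supernodes class-pure keeps the coarse graph a valid 2-HN, and
   co-assigning a module's two supernodes at the start of the next
   level preserves mQ exactly across levels (verified to 1e-10 in the
   tests).

Levels alternate until a level's gain falls below `min_gain` (default
1e-9), aggregation stops shrinking the graph, or `max_levels` (20) is
reached. A final local-moving pass on the original network then
polishes the projected partition: stability at a coarse level does not
imply single-node stability on the fine graph, and the polish restores
that guarantee at negligible cost. Ties between candidate moves keep
the earlier candidate in sweep order, and moves require strictly
positive gain, which prevents oscillation; determinism under a fixed
seed is tested.

Initialization is every node in its own module. The search is greedy
and single-restart: on rugged instances it can stop in a local optimum
slightly below the best known partition, which is inherent to this
optimizer class; no restart schedule is built in.

## The benchmark generator

`generate_benchmark` plants mixed modules in five steps:

1–2. Two LFR-style subnetworks. Degrees follow a truncated power law
   (exponent `tau1`, default 2) whose lower cutoff is solved so the
   mean matches `k`, then the sampled sequence is nudged to hit the
   target mean exactly. Community sizes follow a truncated power law
   (exponent `tau2`, default 1) on `[max(10, maxk/2), N/5]`. Each node
   receives an internal degree by *stochastic* rounding of (1−μ)·d —
   deterministic rounding systematically underestimates the realized
   mixing at small degrees — and nodes are placed in communities large
   enough to host their internal degree. Internal stubs are paired per
   community and external stubs globally (forbidding same-community
   pairs), with conflict repair by edge swaps; the handful of
   unrepairable pairs is dropped. Realized mean mixing tracks the
   requested μ within ±0.05 at the default sizes (tested over 10
   seeds).
3. Communities are grouped into nc = min(n_A, n_B) mixed modules,
   uniformly over all groupings that give every module at least one
   community from each side: the side with exactly nc communities is
   assigned by a random bijection, the other by an exactly uniform
   random surjection (sampled via a Stirling-number recursion; the
   distribution over the 14 valid assignments for n_A=2, n_B=4 is
   verified by enumeration).
4. round(kPi·N_A) bipartite edges are drawn; each falls inside one
   planted module with probability p (module chosen proportional to
   its |A_c|·|B_c| pair count, endpoints uniform within it) and between
   arbitrary endpoints otherwise; duplicates are resampled. *p* is
   interpreted per drawn edge, not per node pair — a per-pair Bernoulli
   would make density explode with module size.
5. The integrated 2-HN is emitted with a planted module label per node.

Optionally one channel is weighted by the weighted-LFR scheme: target
node strength d^β (β default 2), a fraction 1−μ_w of it carried by
intra-module edges. Edge weights start at the mean of their endpoints'
per-edge target shares and are refined by 25 rounds of multiplicative
proportional fitting; realized node strengths track d^β and realized
weighted mixing tracks μ_w within ±0.05 (tested). When μ_w is not
given it defaults to the channel's own topological mixing (μ_A for the
A channel, μ_B for B, 1−p for the bipartite channel).

### Free parameters the original study does not pin down

The bipartite edge budget is not stated anywhere; this implementation
exposes it as `kPi`, the mean bipartite degree per A node, default 4.
The LFR community-size bounds and exponents are likewise unstated;
the defaults above are conventional choices. These choices matter
quantitatively: with kPi = 4 and p = 0.5 each A node carries on
average only ~2 within-module bipartite edges, so when μ_A is large
(its own channel uninformative) the cross-class glue of a planted
module is weak and mQ maximization legitimately splits modules. In the
standard sweep (p = 0.5, μ_B = 0.2, μ_A ∈ {0.2,…,0.8}, 10 networks per
point) this yields mean NMI ≈ 0.78–0.80 and mean CA ≈ 0.87 — recovery
is near-perfect at μ_A = 0.2 (NMI ≈ 0.96) and degrades to NMI ≈ 0.6 at
μ_A = 0.8, rather than staying flat near 0.9 as under a denser
bipartite regime. The detected partitions score at or above the
planted partition's mQ on every cell of the sweep, so this profile is
a property of the generated landscape, not an optimizer artifact. A
larger kPi strengthens the cross-class coupling and flattens the
curve; kPi is deliberately left at its documented default rather than
calibrated against any external number.

### What the generator does not emulate

Real chemical–gene networks have hub target genes shared across many
modules, multi-label nodes, isolated components, and channel densities
far from any LFR regime; the generator produces none of these. Passing
recovery tests on these benchmarks demonstrates correctness of the
quality function and search under controlled planted structure, not
performance guarantees on curated databases.

## Metrics

- **NMI** uses the confusion-matrix normalization with natural
  logarithms (−2 Σ N_ij ln(N_ij N / N_i· N_·j) over the sum of marginal
  entropies). Zero cells contribute 0; if both partitions are a single
  module the value is defined as 1 (they are identical); if exactly one
  is trivial the denominator convention yields 0. The formula is
  cross-checked against an independent arithmetic-mean NMI
  implementation.
- **CA** builds the same confusion matrix and takes the one-to-one
  module matching maximizing total overlap (Hungarian assignment),
  divided by the node count; a greedy matcher is available for
  comparison and never exceeds the optimal one. Unmatched modules
  contribute zero overlap; the denominator is always N.
- Multi-label ground truth (a minority of curated genes belong to
  several clusters) is resolved before scoring: each multi-label node
  takes the candidate label most represented by single-label nodes in
  its found module, falling back to the smallest candidate.

## Application-network construction

- Similarity edges: all chemical pairs with fingerprint Tanimoto
  coefficient ≥ 0.7 (inclusive). Edges carry weight 1 by default — the
  similarity value is available as an optional weighted mode — since
  the similarity scale is not commensurable with database counts.
- Gene–gene edges: one edge per pair present in at least one source
  database, weighted by the number of distinct databases (1–3 for the
  three-database setting); duplicates within a database count once.
- Chemical–gene edges are taken as curated; duplicate rows are
  rejected rather than summed, since stacking counts across sources
  would silently inflate weights from curation overlap.
- The similarity–interaction test computes, over all chemical pairs,
  Spearman's ρ between fingerprint similarity and the number of B–B
  edges joining the two chemicals' target sets plus the number of
  shared targets (a shared target being the strongest coupling two
  target sets can have; both components can be toggled). P-values use
  the large-sample approximation with midrank ties.
- The label permutation test scores curated cluster labels by mQ and
  compares against labels shuffled *within each node class*, so class
  sizes and each class's label profile are preserved and the test
  isolates module structure rather than class balance; empirical
  p = (1 + #{null ≥ observed}) / (n_perm + 1).

## Numerical and interface conventions

- Node ids are opaque strings; input networks are simple (no self-loops
  or parallel edges); weights must be strictly positive; channel
  membership is derived from endpoint classes and never stored.
- Canonical file formats are TSV: node tables (`node_id`, `class`,
  optional integer `module` ground-truth column), edge tables (`u`,
  `v`, optional `weight`), partition tables (`node_id`, `module_id`),
  and a coarse module-network export with class-pure supernodes,
  self-loop weights and intra/inter-module flags.
- Partition module ids are canonicalized to contiguous integers in
  order of first appearance over sorted node ids, so partitions compare
  by their blocks, not their labels.
- Gain comparisons use strict `>` with no epsilon; level convergence
  uses `min_gain` = 1e-9 on the total mQ improvement of a level.
- All randomness flows through explicit integer seeds; generation,
  detection and the permutation test are bit-reproducible for a fixed
  seed.

## Known limitations

- Exactly two node classes; no overlapping modules; no directed edges.
- Single-restart greedy search (see above); modularity-family methods
  inherit the resolution limit within each channel.
- The sweep sizes used in the test suite and the reproduction script
  (400 + 600 nodes, 10 replicates per grid point) are the package's
  standard benchmark configuration; results at much larger scales are
  not characterized here.
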