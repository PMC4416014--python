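# mixmod

Mixed-modularity module detection for 2-class heterogeneous networks
(2-HNs) — the integrated chemical–gene networks of network pharmacology,
where chemical–chemical similarity, chemical–gene interaction and
gene–gene interaction are three differently-sourced edge channels over
two node classes.

## Who this is for

Systems-biology and network-pharmacology practitioners who have (or can
simulate) a network with two node classes A and B — drugs/chemicals and
gene targets in the motivating applications — and want to find **mixed
modules**: communities containing nodes of both classes, interpreted as
groups of chemicals that act synergistically on an interacting group of
genes. Classic community detection treats all edges alike; because the
three channels of a 2-HN come from different sources with incomparable
densities and weight scales, pooling them lets one channel drown out the
others.

## The quality function

A 2-HN is G = (V, E) with V = {V_A, V_B} and E = {E_AA, E_AB, E_BB},
decomposed into subnetworks G_A, G_Π (bipartite) and G_B. Each module
*c* of a partition is virtually split into three submodules — its A–A,
A–B and B–B parts — and each is scored within its own channel:

```
mQ = (1/3) Σ_c { [ l_Ac/m_A − (d_Ac / 2 m_A)² ]
               + [ l_Πc/m_Π − k_Πc d_Πc / m_Π² ]
               + [ l_Bc/m_B − (d_Bc / 2 m_B)² ] }
```

where l_Xc is the internal weight of module *c* in channel X, m_X the
channel total, d_Ac/d_Bc the summed within-channel degrees of the
module's members, and k_Πc / d_Πc the summed bipartite degrees of its A
and B members. The two outer brackets are Newman–Girvan modularity on
G_A and G_B; the middle is Barber bipartite modularity on G_Π; mQ is
their arithmetic mean over a shared partition. Weighted networks use
strengths throughout. Because every term is normalized per channel, mQ
is invariant under any positive rescaling of a single channel's weights
— the heterogeneity of an integrated 2-HN cannot bias the partition.

**MixMod** maximizes mQ with a Louvain-style two-phase search: greedy
single-node moves to the best neighboring module, then aggregation of
each module into up to two *class-pure* supernodes (so the coarse graph
is again a valid 2-HN and the same quality function applies at every
level), repeated until the score stops improving.

The package also provides:

- a labeled benchmark generator: two LFR-style subnetworks (power-law
  degrees and community sizes, mixing parameters μ_A, μ_B), communities
  grouped into planted mixed modules, bipartite links placed within a
  planted module with probability *p*, optional weighted-LFR weighting
  of one channel (strength ∝ degree^β, weight mixing μ_w);
- evaluation metrics: normalized mutual information (confusion-matrix
  form, natural log) and classification accuracy (maximum-overlap
  one-to-one module matching);
- application-side construction: Tanimoto-threshold similarity edges,
  database-count weighted gene–gene edges, the similarity–interaction
  Spearman test and a label permutation test;
- a sweep harness and a thin `mixmod` command-line interface
  (`generate`, `detect`, `score`, `evaluate`, `sweep`, `build-net`,
  `corrtest`, `permtest`).

## Worked example

```sh
python examples/02_detect_modules.py
```

```
benchmark: HetNet(400 A + 600 B nodes, 5985 edges), 9 planted mixed modules
levels run: 4; per-level mQ: 0.5814, 0.6179, 0.6179, 0.6181
detected 9 modules (9 mixed, 0 single-class), mQ=0.6181
NMI vs planted labels: 0.9598
CA  vs planted labels: 0.9800
```

A 1000-node benchmark 2-HN with nine planted mixed modules is generated
(μ_A = μ_B = 0.2, p = 0.7); the search improves mQ level by level and
returns nine mixed modules whose agreement with the planted partition
is NMI 0.96 / CA 0.98 — near-perfect recovery, as expected for this
clear module structure. The other examples score a hand-built toy
network (`01`), sweep the bipartite coupling p and show recovery
improving with it (`03`), and build a synthetic chemical–gene network
from raw fingerprint/interaction tables, reproducing the positive
similarity–interaction correlation and a significant label permutation
test (`04`).

Equivalent shell usage:

```sh
mixmod generate --mua 0.2 --mub 0.2 --p 0.7 --seed 42 --out-prefix bench
mixmod detect --nodes bench.nodes.tsv --edges bench.edges.tsv --seed 42 --out part.tsv
mixmod evaluate --nodes bench.nodes.tsv --found part.tsv
```

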