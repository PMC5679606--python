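# Methods

## Model

A PPI network is an undirected simple graph *G = (V, E)*: proteins as
nodes, experimentally detected physical interactions as edges, self-loops
and duplicate records removed. Connected components of three or fewer
proteins are dropped during curation — they interact only among themselves
and contribute nothing to network-propagated scores.

DiffSLC scores each node as a convex-style mixture of two terms:

* **Biased degree centrality (BDC).** Each incident edge contributes
  `β · coexpr + (1 − β) · ECC`. The coexpression term rewards interactions
  whose partners are transcriptionally coordinated; the edge clustering
  coefficient `ECC = (z + 1)/min(k_u − 1, k_v − 1)` rewards edges embedded
  in triangles relative to the maximum number of triangles the edge could
  join given its endpoint degrees.
* **Eigenvector centrality (EC).** The principal eigenvector of the
  adjacency matrix, which ranks a low-degree node highly when its few
  neighbors are themselves central — exactly the essential proteins degree
  centrality misses.

`DiffSLC(u) = ω·EC(u) + (1 − ω)·BDC(u)`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.8 | weight of coexpression vs ECC inside BDC (dimensionless, [0, 1]) |
| ω | 0.1 | weight of EC vs BDC (dimensionless, [0, 1]) |
| coexpression measure | dCor | pearson / spearman / dcor |
| ECC denominator | degree | degree / triangles |
| EC/BDC normalization | ec_max | ec_max / minmax |
| closeness mode | harmonic | harmonic / classic |

The β = 0.8, ω = 0.1 defaults follow the configuration used for the
distance-correlation-weighted analyses; because different expression
datasets favor different optima (and published accounts of the best ω are
not mutually consistent), both parameters are plain arguments everywhere
and a full (β, ω) AUC sweep is a first-class operation rather than a
hard-coded choice.

Distance correlation is the default coexpression measure because it is
non-negative (a signed measure would let anticorrelated partners *reduce* a
node's score; an `absolute` option covers that for Pearson/Spearman) and
because it detects non-monotone dependence. It is computed with the
standard univariate double-centering estimator on |xᵢ − xⱼ| distance
matrices; the characteristic-function formulation is the population
definition, not the algorithm. If either distance variance is zero the
value is 0 by convention.

## Numerical choices

* **ECC denominator.** `k` is the endpoint *degree*, making
  `min(k_u − 1, k_v − 1)` the ceiling on the edge's triangle count; an
  alternative mode uses the endpoints' own triangle counts. Pendant edges
  (degree-1 endpoint) get ECC = 0: such an edge can join no triangle and
  should carry no clustering bias.
* **Closeness.** The harmonic form `Σ 1/d(u, v)` with unreachable pairs
  contributing 0; it is well defined on the disconnected graphs real
  interactomes produce. A classic inverse-farness mode is available.
* **Betweenness.** Unnormalized, over unordered pairs excluding the
  endpoint itself.
* **Eigenvector centrality.** Deterministic power iteration (uniform start
  vector, tolerance 1e−12 on successive normalized iterates, cap 10⁶
  steps) on A + I — the shift leaves eigenvectors unchanged but prevents
  oscillation on bipartite-like components. The vector is rescaled to max
  entry 1; nodes outside the dominant component converge to ~0.
* **Subgraph centrality.** Full symmetric eigendecomposition (the diagonal
  of exp(A)); refused above a 6000-node guard rather than silently
  approximated.
* **EC/BDC commensurability.** EC is naturally ≈ unit scale after max
  normalization while BDC is an unbounded edge sum; the default mixes them
  as-is (`ec_max`). A `minmax` mode rescales both to [0, 1] first, making ω
  a true convex weight — the sweep can be run in either mode.
* **ROC.** Standard (FPR, TPR) axes; thresholds sweep distinct score
  values, so tied nodes cross together and tie order cannot inflate the
  AUC; the trapezoid AUC then equals the Mann–Whitney statistic with ties
  counted ½. Precision at zero predictions is undefined and omitted, not
  imputed. Top-k% slices use ⌊pN/100⌋ nodes.
* **Tie-breaking.** All rankings order by descending score, then ascending
  node identifier.
* **ID mapping.** Interactors resolve to probesets via UniProtKB first,
  then Ensembl; with several candidate probesets the one with the lowest
  *mean* expression across samples wins (a conservative floor on the
  transcription any candidate underwent; a `min` selector is provided).
  Unmapped interactors stay in the network with coexpression 0 on their
  edges — the ECC term still contributes — and are recorded, never dropped
  silently.
* **Labels.** Every gene absent from the essential list is labeled
  non-essential; no unknown class, so measured performance is a
  conservative lower bound.

## Synthetic data

The fixture generator produces the coupled artifacts a real study needs:

* **Network** — preferential attachment (scale-free-like, hubs present),
  default 2000 nodes with 3 edges per arrival; optional 2–3-node satellite
  components exercise the curation filter.
* **Essentiality** — each node essential with probability logistic in its
  standardized degree; the slope (`degree_bias`, default 1.5) sets the
  strength of the centrality-lethality link and the intercept is solved so
  the expected essential fraction hits its target (default 0.2, the
  approximate fraction of essential genes among curated yeast interactome
  proteins).
* **Expression** — 36 samples per gene (a dense time-course scale),
  unit-variance Gaussian noise plus a variance-normalized sum of shared
  per-edge latent factors; edges touching an essential node carry 4× the
  relative factor weight, scaled overall by `edge_coexpr_boost` (default
  0.6). Per-node normalization keeps hub profiles from being dominated by
  their own factor sums; a consequence is that per-edge correlation
  dilutes with degree, which matches the budget a single transcript has
  for co-regulation with many partners. One probeset per node, plus
  configurable unmapped nodes and higher-expressed decoy probesets to
  exercise the lowest-expression mapping rule.

Everything is deterministic under the seed.

What the generator does **not** emulate: microarray noise structure
(probe effects, RMA artifacts), co-complex modularity beyond pairwise edge
factors, correlated measurement error between samples, or the literature
biases of curated interactomes. Passing recovery tests therefore shows the
method extracts exactly the kind of signal it models — degree-linked
essentiality plus edge-local coexpression — not that it will reach any
particular AUC on a real interactome.

## Problem sizes

The test suite and the acceptance script run the recovery analyses on
2000-node fixtures (10–20 seeds) and the exhaustive oracle comparisons on
graphs of up to 50 nodes, sizes at which brute-force enumeration is exact
and the full suite completes in a few minutes on one CPU.

## Limitations

* The method ranks; it does not calibrate probabilities of essentiality.
* Negative Pearson/Spearman edge weights pass through unmodified unless
  `absolute` is requested; with many anticorrelated edges BDC can rank a
  hub below its degree peers by construction.
* Subgraph centrality requires a dense eigendecomposition and is guarded
  above 6000 nodes.
* No significance machinery for AUC differences (a bootstrap CI helper
  exists but is off by default); comparisons between methods are point
  estimates.
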