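# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic study conditions do and do not establish.

## Network model and metric conventions

Networks are undirected simple graphs over opaque, case-sensitive protein
identifiers; no self-loops, no parallel edges, no identifier
normalization. Condition layers are induced subgraphs of one master
interactome, so normal/disease differences arise only from node
membership. A confidence-scored interactome is thresholded with a strict
`>` at 0.50 by default (configurable); proteins named in a layer list but
absent from the interactome are kept as isolated nodes (count logged,
`drop` available), so a layer's `N` counts proteins rather than connected
proteins.

Conventions that fix reported magnitudes:

* **Betweenness** (node and edge): Brandes sums over unordered
  source–target pairs, endpoints excluded, unnormalized. Correlations
  built on these are scale-invariant, so the choice affects absolute
  values only.
* **Clustering**: `CC_i = 0` for nodes of degree < 2, included in ⟨CC⟩
  (exclusion available via a flag); the denominator of the average is a
  convention, not a fact about the network.
* **Diameter**: computed on the largest connected component; ties between
  equal-sized components break toward the one containing the
  lexicographically smallest node; the LCC fraction is always reported so
  the convention is visible.
* **Assortativity**: the edge-sum (Newman) formula over each undirected
  edge once, endpoint order symmetrized by half-sums. A vanishing
  denominator (any regular graph) yields NaN — undefined correlations are
  never coerced to 0.
* **Neighborhood overlap**: `O_ij = n_ij/((k_i−1)+(k_j−1)−n_ij)`;
  undefined (NaN) for mutually pendant edges, which are excluded from
  correlations and weak-tie selection with a logged count.

## Spectral degeneracy and duplication

For a 0/1 adjacency matrix the multiplicity of eigenvalue 0 equals
`N − rank(A)` and that of −1 equals `N − rank(A + I)`; both are computed
as integer rank deficiencies (SVD with the standard `N·ε·σ_max`
threshold), which is exact for integer matrices and immune to tolerance
drift. An independent eigenvalue-binning count (tolerance
`1e-8 · max(1, σ_max)`) must agree or the function raises — numerical
pathology is surfaced, never hidden.

A class of `c` nodes with identical open neighborhoods contributes `c − 1`
zero eigenvalues; a class with identical closed neighborhoods contributes
`c − 1` eigenvalues at −1. The package detects these classes by canonical
neighbor-set hashing (O(N+E) expected) and reports the degeneracy bounds
they imply. Partial duplicates (rows equal to sums of other rows) are not
enumerated — the search is combinatorial — and their presence is instead
inferred as the slack `count_zero − bound_zero`. Consequently the −1
degeneracy is interpreted as a *bound* related to adjacent twins, not a
clique count.

## Null models

ER matches use `p = ⟨k⟩/N` exactly (not `/(N−1)`); the induced small bias
is the convention this pipeline standardizes on. Configuration matches
pair stubs uniformly; the default `erase` scheme deletes self-loops and
collapses multi-edges afterwards (on the 500-node reference interactome
this loses about 2% of edges, always logged), while the `rejection` scheme
resamples until the pairing is simple and preserves the degree multiset
exactly — practical only for sparse sequences, and it errors with advice
after a capped number of attempts. Ensembles default to 20 realizations;
realization `i` draws its seed from a spawned `SeedSequence`, so runs are
reproducible and independent of metric choice.

## Two-regime power-law fit

The empirical degree density is log-binned with edges snapped to integers
(≈ 6 bins per decade), so no bin is narrower than one degree — fractional
bins would otherwise inflate the density at small `k`. Bins holding fewer
than 5 observations are dropped, and each segment line is fitted by
least squares weighted by bin occupancy, reflecting the ≈ 1/count variance
of a log-density estimate; without these two choices the sparse tail bins
dominate and the low-regime exponent is biased upward by ≈ 0.3. The
breakpoint is chosen by total weighted SSE over all splits leaving ≥ 3
bins per side (ties → smaller breakpoint); continuity at the break is not
enforced. The procedure recovers exponents (1.2, 3.0) and a break at 20
within ±0.3 and ×1.5 on 5000-sample draws from an exact piecewise law.
No maximum-likelihood machinery or model comparison is attempted — the fit
is a descriptive two-scale summary, not a hypothesis test.

## Weak ties and candidate screening

No principled numeric cutoff exists for "high `β_L`, low `O`", so both are
quantile thresholds (defaults 0.9 and 0.1 over defined-`O` edges) and the
full ranked edge table is always emitted. When neither metric varies
across edges (e.g. a complete graph) no edge is distinguished and the
selection is empty; the same rule applies to the node screen when
betweenness is constant. The node screen takes `β_c` ≥ its 0.9 quantile
and `k` ≤ its median, quantiles over all layer nodes; cross-layer
candidates must pass in ≥ 4 layers (mirroring a seven-layer design where
four is a majority) and, by default, touch an extracted weak tie in at
least one layer.

"Common" means present in the node set of *every* layer of a condition;
the across-condition common set is the intersection of the two
per-condition sets, with the union also exposed. The subset-clustering
ratio uses `CC_i` computed in the full layer, averaged over the common
set (an induced-subgraph variant sits behind a flag).

## Synthetic study conditions

The generator provides the statistical structure the analysis assumes,
with full ground truth:

* **Master interactome** (`N0 = 500`): ten duplication–divergence modules
  on a ring, adjacent modules joined by two random edges. Within a module
  each new protein copies a uniformly chosen progenitor, keeps each
  inherited interaction with probability 0.55, keeps *all* of them with
  probability 0.10 (an exact duplicate), and gains the
  duplicate–progenitor cross-link with probability 0.85. Subcritical
  retention keeps ⟨k⟩ near 8; the frequent cross-link makes low-degree
  nodes highly clustered, producing the negative `k–CC` correlation of
  hierarchical PPI networks; the modular ring keeps the diameter roughly
  twice the ER match and concentrates inter-module traffic on few edges.
* **Plants**: 5 exact-duplicate clone pairs; 6 connector nodes, each
  wired to the top hub of three mutually non-adjacent modules (degree 3,
  top-decile betweenness in every layer — the planted "sensors"); 5
  bridge edges between high-degree, neighborhood-disjoint nodes of
  non-adjacent module pairs, with no module pair reused by any plant, so
  each shortcut is the unique direct route between its modules.
* **Layers**: 7 tissues × {normal, disease}; each layer contains its
  condition's planted common set (63 disease / 19 normal / 8 both —
  connectors, anchors and bridge endpoints live inside the disease set so
  they persist across disease layers) plus a Bernoulli(0.6) sample of the
  remaining proteins. Any *accidental* all-layer-common node is then
  removed from one randomly chosen layer, so the planted Venn structure
  is recovered exactly by construction rather than with high probability.

What passing tests show — and do not. The generator reproduces the
qualitative regularities of real interactomes (heavy tail, high
clustering, duplication-driven zero modes, modularity with weak ties),
so green tests demonstrate that the pipeline *measures and recovers these
structures correctly*. They do not certify performance on real data,
where identifier noise, study bias in edge coverage, and confidence-score
artefacts dominate; nor does the generator imitate any particular
dataset's `N`/`N_C`. Two real-data signatures — common proteins with
about twice the network's mean OUT connectivity and about twice its ⟨CC⟩
— presuppose a sparse, low-clustering baseline; on this generator's
high-clustering reference conditions they cannot both arise, so those
measurements are validated on dedicated fixtures that realize their
premises instead.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline fans one
master seed out to per-stage children by stable hashing of stage names,
so adding a stage never perturbs another's randomness, and reruns are
byte-identical. Reference problem sizes — a 500-protein master, 14 layers
of ≈ 330 proteins, 20-realization ensembles, 10-seed recovery
experiments — were chosen so the full synthetic study reads clearly and
runs comfortably on a laptop; all are configuration fields.

## Known limitations

* Dense eigensolves and exact diameters assume desk-scale networks (a
  warning fires above N = 5000); for genome-scale interactomes the
  spectral suite needs sparse methods not included here.
* The weak-tie and screening thresholds are descriptive quantiles; they
  rank, they do not test significance.
* Relation types (physical vs functional) are collapsed onto one edge
  kind; identifier mapping across databases is a user concern.
* The multilayer formalism is set arithmetic over layers — no interlayer
  edges or supra-adjacency operators.
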