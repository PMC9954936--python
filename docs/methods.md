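# Methods

## Extended persistence on vertex-filtered graphs

A vertex-filtered graph is a simple undirected graph `G=(V,E)` with a filter
`f: V → R`.  Filters extend to edges by `f(e) = max` of the endpoint values in
the ascending (sublevel) pass and `min` in the descending (superlevel) pass.
Each vertex and edge contributes one *algebraic simplex* per pass; the
filtration order sorts the ascending block by `(value, vertex-before-edge,
index)` and the descending block by `(−value, vertex-before-edge, index)`.
The theory assumes an injective filter; the deterministic tie rules extend
every operation to arbitrary filters so outputs are always well defined and
reproducible, at the cost of the output being only one of the valid pairings
when ties occur (gradients at ties are one-sided but finite).

The boundary matrix uses the cone construction: ascending vertices bound
nothing; ascending edges bound their endpoints; a descending vertex bounds
its ascending copy; a descending edge bounds the ascending edge plus both
descending endpoints.  Reduction is the plain left-to-right column algorithm
over Z2 (worst case `O(n³)` in `n = |V|+|E|`), with columns stored as sparse
integer sets; no twist/clearing optimizations are applied because graph
instances here are small and exactness, not throughput, is the point.  For
graphs the reduction pairs every simplex, so the four diagrams `Ord0, Ext0,
Ext1, Rel1` contain only finite coordinates.

Diagram points store **raw filter values**; the reversed order of the
descending axis is expressed by the per-class birth/death inequality
(`birth ≤ death` for `Ord0`/`Ext0`, `birth ≥ death` for `Ext1`/`Rel1`), never
by negating stored numbers.  This keeps L1 distances between points and
coordinate-function centers meaningful.

The *locating map* sends every vertex simplex to its own vertex and every
edge to whichever endpoint enters later in the edge's own pass — under
injectivity the argmax-f endpoint ascending and the argmin-f endpoint
descending.  A diagram point's coordinates are exactly the filter values at
the locating vertices of its birth and death simplices, which is what makes
the layer differentiable.

### Independent oracle

The matrix reduction is cross-checked against a reduction-free computation:
`Ord0` by an elder-rule union-find sweep, `Rel1` by the same sweep of `−f`
(the descending pass of `f` replays the ascending pass of `−f`, so the finite
0-dim classes of `f` and `−f` swap roles with coordinates negated in place),
`Ext0` as `(min f, max f)` per connected component, and the `Ext1` birth and
death coordinate multisets as the ascending / descending cycle-edge entry
values.  The oracle cannot see which `Ext1` birth pairs with which death —
recovering that matching is precisely the extra information extended
persistence carries — so `Ext1` is compared as two value multisets.

## The layer

Shapes: input dim `d` (default 64), `df` filter functions (default 8),
vectorization dim `dv` (default 32), output dim `d_out` (default `d`, so
layers stack).  The filtration module is a GIN-ε convolution
(`h = MLP((1+ε)x + Σ_neighbors x)`, ε learnable and initialized at 0 — left
open in the source material, a learnable ε strictly generalizes a fixed one),
a concatenation skip `[x ‖ h]`, a two-layer MLP to `df` outputs, and a
logistic sigmoid so filter values live in (0,1); coordinate-function centers
are initialized in `(0,1)²` to match that range.

Vectorization learns `dv` rational-hat coordinate functions **per diagram
class** (4·`dv` total), shared across the `df` filtrations — the parameter
budget is therefore independent of `df`.  The hat
`s(p) = 1/(1+‖p−c‖₁) − 1/(1+||r|−‖p−c‖₁|)` peaks at `c` with height
`1 − 1/(1+|r|)`, dips negative near L1 distance `|r|` from `c`, and vanishes
identically when `r = 0` (both terms coincide), which provides a clean
degeneracy test: with all `r = 0` the aggregated block is exactly zero.

Aggregation adds each point's vector to the nodes located at its birth and
its death simplex (a point whose two locations coincide contributes twice),
keeps one accumulator per filtration and concatenates them
(`df·dv` per node), then batch-normalizes over the node axis and applies
ReLU.  Concatenation rather than summing across filtrations is the default
because it preserves per-filtration information ahead of the final FC; a
`sum` mode is available as a config switch, as is an additive
(project-then-add) residual instead of the default residual-by-concatenation.
Batch statistics are computed over all nodes of a mini-batch (a disjoint
union of graphs); persistence itself is always computed per member graph.
At evaluation time batch norm uses running statistics.

Differentiation treats the pairing and locating maps as locally constant:
gradients flow only through the filter values at located vertices, which is
the correct derivative wherever the filters are injective.  The package
ships a small reverse-mode automatic-differentiation tape over numpy
(`treph.autodiff`) on which the layer, the GNN backbones and training run;
`gradcheck` compares its gradients against central finite differences
(step 1e-6) and agrees to ~1e-9 relative error at injective filter values.

### Ablation variants

Both variants replace EPH by ordinary persistence of `f` and `−f`, read off
the extended diagrams through the exact projection (`Ext0 → (min, ∞)` points
of `f` and `(−max, ∞)` points of `−f`; `Ext1` likewise in dim 1):

* **noext** keeps finite 0-dim points planar (same treatment as the full
  layer) and vectorizes each essential point `(a, ∞)` as the scalar `a` with
  `dv` one-dimensional hat functions per essential family, assigning the
  vector only to the birth location;
* **noext-trunc** replaces each `(a, ∞)` of `f` (resp. `−f`) by
  `(a, max f)` (resp. `(a, max(−f))`), vectorizes all points uniformly in the
  plane, and aggregates every vector to its birth location only.

Both variants discard the min–max matching; on a graph pair with identical
ordinary persistence of `±f` they produce identical outputs under any shared
parameters, while the full layer separates such pairs for generic parameters.
These comparisons feed the pair's own filter values (scaled monotonically
into (0,1)) through the layer's fixed-filtration mode: a *learned* filtration
given uninformative all-ones features is constant on 2-regular graphs, which
collapses every diagram to the diagonal and would void the comparison.

## Synthetic data

`random_graph(n, m, seed)` draws uniform simple graphs with i.i.d. uniform
(0,1) filter values (re-drawn to injectivity on request); oracle-equivalence
checks run on 200 such graphs with `n ≤ 30`.  `loop_count_task` generates
balanced connected graphs of matched size (8 vertices by default) labelled by
the first Betti number 0/1/2 — random labelled trees plus 0, 1 or 2 extra
chords — with uninformative all-ones node features, so only structure is
informative and the number of `Ext1` points equals the label.  The generator
emulates the structural-capacity setting of small-molecule-scale benchmark
graphs, not their degree distributions, edge densities or label noise;
passing it shows the layer extracts loop structure end to end, not that it
matches benchmark accuracies.

## Training protocol and problem sizes

Training uses Adam at 1e-3, halving the learning rate when validation
accuracy has not improved for 10 epochs, stopping below 1e-5 or at 200
epochs; cross-validation is 10-fold with 10% of each training split held out
for validation; cross-entropy loss, mean pooling, and a two-layer MLP head
with hidden width 32.  The loop-counting experiment uses 300 graphs, a
4-layer GIN with the topological layer first, hidden width 16, `df=2`,
`dv=8`, mini-batches of 32, and stops early once training accuracy reaches
100% (the quantity of interest); it converges in well under the 200-epoch
cap.  These widths are deliberately small: the task is linearly separable in
the aggregated topological features, so capacity adds nothing but runtime.

## Known limitations

* Homology is computed for graphs only (dims 0 and 1); no simplicial or
  cubical complexes, and no GPU/CUDA reduction.
* The reduction is exact but cubic in the worst case; very large dense graphs
  will be slow.
* With non-injective filters the deterministic tie-break picks one valid
  pairing; outputs are reproducible but not permutation-equivariant at ties,
  and gradients there are one-sided.
* TU benchmark loading is supported, but benchmark accuracies depend on
  external downloads and long stochastic training runs and are out of scope
  for the test suite.
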