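# Methods

## Graph model

A knowledge graph is an undirected simple graph G = (V, E) with a total
type map φ: V → A over a set of node-type labels A. Node ids are opaque
strings and must be globally unique across types; the triple loader
prefixes OGB-style per-namespace indices with their entity type
(`drug:7`, `protein:7`) to guarantee this. Edge direction and edge types
are deliberately not modeled: meta-paths here constrain node types only,
and directed input relations (e.g. reciprocal triples) symmetrize to a
single undirected edge on load.

Construction drops self-loops and collapses duplicate edges, with counts
kept on the graph object and logged. Self-loops can never participate in a
conforming path under the repeat-free rule; duplicate edges would silently
multiply path counts, since counting is over node sequences, not edge
multisets. Nodes that appear in the type table but in no edge are retained
with degree 0, so typed-degree queries are total.

Typed neighbor queries are answered either by scanning the edge list or
from a precomputed per-node, per-type adjacency index; both backends
return identical, lexicographically sorted lists, and the index carries a
SHA-256 content fingerprint of its source graph so a stale cache is
detectable. Sorted neighbor lists make every enumeration order and every
output file deterministic without any seed.

## Path semantics

A meta-path is a sequence of L+1 type labels describing L edges;
palindromic meta-paths (equal to their reversal) are the domain of
PathSim. Enumeration expands the type sequence from the origin with an
explicit-stack DFS (no recursion-depth limit on meta-path length) and
emits paths in lexicographic order.

Two semantics are exposed:

- **paths** (default): no node id occurs twice, *except* that the first
  and last node may coincide. This blocks degenerate back-and-forth
  inflation (u–x–u–x–…) while keeping round trips well defined.
- **walks** (`allow_repeats=True`): no restriction. Walk counts factor
  through linear algebra — the count from u to v equals the (u,v) entry of
  the product of per-step typed biadjacency matrices — which is exactly
  how the test-suite cross-checks the DFS against an independent
  scipy.sparse implementation.

Wildcard queries (origin or destination = `any`) count all conforming
paths leaving or entering a node; a wildcard count is capped at 10⁶ paths
per origin and the result is flagged `truncated`, never silently cut.
Pair queries are uncapped by default.

## Metrics

Let PC(u,v|M) be the number of conforming path instances.

- **PC** — the raw count; repeat-free semantics.
- **NPC** = 2·PC(u,v|M) / (PC(u,\*|M) + PC(\*,v|M)), with PC(u,\*) the
  wildcard count out of u along M and PC(\*,v) the count into v (equal to
  the wildcard count out of v along reversed M); 0/0 → 0. The factor-2
  form is used (rather than a plain ratio) so that the score reaches 1
  exactly when every path out of u and every path into v connects the
  pair; the score is always ≤ 1 because the (u,v) paths are contained in
  both marginals. This normalization follows the hetnet edge-prediction
  literature (Himmelstein & Baranzini 2015, *PLoS Comput Biol* 11:e1004259).
- **DWPC** = Σ over paths p of the path-degree product
  PDP(p) = Π over consecutive pairs (nᵢ, nᵢ₊₁) of
  [d_{Tᵢ₊₁}(nᵢ) · d_{Tᵢ}(nᵢ₊₁)]^(−w). Degrees are **typed** degrees with
  respect to the meta-path's step types, not total degrees — the choice
  most likely to differ between implementations, so it is pinned by
  brute-force oracle tests. Every traversed edge contributes two factors
  ≥ 1, hence PDP ∈ (0,1] and DWPC ∈ [0, PC]. w = 0 reduces exactly to PC
  (any real implementation must satisfy this identity; it is tested
  exactly, not approximately). Default w = 0.4, the damping adopted in the
  source literature; exposed as `--dwpc-w`.
- **PathSim** = 2·PC(u,v|M) / (PC(u,u|M) + PC(v,v|M)) for palindromic M;
  0/0 → 0. PathSim is computed over **walk** counts (Sun et al. 2011,
  *PVLDB* 4:992–1003). This is a deliberate semantic split from the other
  metrics: under repeat-free counting the bound PathSim ≤ 1 fails — a
  cross pair can be connected (u–b–c–b′–v) while *no* round trip u→u
  exists, because the return leg would have to reuse b — producing a
  positive numerator over a zero denominator. Under walk counts the score
  matrix is a Gram matrix (W·Wᵀ for the half-meta-path walk matrix W), so
  2·xᵤᵥ ≤ xᵤᵤ + xᵥᵥ always holds. A non-palindromic meta-path is an
  error by default; with `force=True` (CLI `--force`) the round trip
  M ∘ reverse(M) is scored instead.

All metrics return the supporting path count alongside the score, and all
return 0 (never an error) when no paths and no normalizing paths exist.
Custom metrics register by unique name and receive the enumerated paths
plus a context answering typed-degree and wildcard-count queries; the
context caches per-pair enumerations so scoring several metrics on one
pair traverses the graph once.

## Set-level aggregation

Set similarity computes the full |A|×|B| matrix of pairwise scores and
reduces it with one of {mean, median, max, min}; mean is the default. The
order-statistic family was chosen as the smallest complete one, and the
pair matrix is always returned so any other reduction can be applied
without recomputation. Duplicate ids within a set are dropped with a
warning to prevent silent double-weighting. Aggregators are symmetric
functions of the score multiset, so member order never matters, and for
reversal-symmetric metrics set_sim(A,B|M) = set_sim(B,A|reverse(M)).

## Synthetic generator

The generator emulates a biomedical KG schema with five node types
(disease, drug, protein, function, side-effect) and Erdős–Rényi topology
per type pair: each admissible node pair carries an edge independently
with a per-pair probability. Defaults are desk scale — 50 nodes per type
with densities 0.02–0.05 (disease–drug 0.05, disease–protein 0.05,
protein–function 0.05, drug–protein 0.03, drug–side-effect 0.03,
protein–protein 0.02) — dense enough that 3–4-step meta-paths have
nontrivial instance counts, small enough that exhaustive oracles remain
cheap. Same-type densities sample each unordered pair once. Identical
spec (counts, densities, seed) yields a byte-identical graph.

What this emulates and what it does not: the generator reproduces typed
sparsity and multi-relational structure, but **not** the heavy-tailed
degree distributions of real biomedical KGs. Oracle-agreement results
therefore establish correctness of the algorithms, not calibration of the
metrics on realistic topology; on a real KG, hub effects will make the
gap between PC and DWPC far larger than on these graphs.

The scaling harness samples graphs stratified by type (total node count
split evenly across the five types), runs a fixed battery of wildcard
count queries from the first 10 origin nodes, and reports counts and wall
times; timings are informational and never asserted. The default battery
spans 250–2500 nodes, sizes at which the full suite runs in seconds.

## Numerical and design notes

- All similarity scores are floats; test comparisons use absolute
  tolerance 1e-9. The identity dwpc(w=0) = pc is exact (integer-valued
  floats), not approximate.
- Tie-breaking everywhere is lexicographic on node ids; output TSVs are
  byte-identical across runs on identical inputs.
- Oracle batteries in the validation suite use 100 random graphs (≤ ~200
  nodes) for matrix-product count equivalence, 40 for simple-path
  enumeration equivalence and 30 for metric formula agreement, with
  meta-paths of 2–5 types drawn by walking the schema's admissible type
  pairs.
- Degenerate inputs: empty edge lists are rejected at load; unknown type
  labels in queries yield empty results (not errors); unknown node ids
  are always errors.

## Limitations

- Edge-type-constrained meta-paths are not supported; meta-paths
  constrain node types only.
- No sampling-based approximate counting: all counts are exact, so very
  dense graphs with long meta-paths can be expensive; the truncation cap
  bounds work but biases any metric computed from a truncated set (the
  flag is propagated into every result).
- No statistical calibration (null models, significance of scores) and no
  all-pairs similarity matrices beyond the set-similarity convenience
  loop.
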