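# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `fgnet`, and what the synthetic-data test bed does and
does not establish about real data.

## Data model

An interactome is a set of typed nodes — `protein`, `small_molecule`,
`functional_class`, `complex`, `cell_process` — joined by typed, signed,
optionally directed relations (`binding`, `protein_modification`,
`direct_regulation`, `expression`, `promoter_binding`, `mol_synthesis`,
`mol_transport`, `regulation`, `chemical_reaction`, `unknown`). Three
conventions are enforced at load time:

- **Simple topology.** Self-loops are rejected: the shortest-path-tree and
  neighbourhood-component algorithms are defined on simple graphs, and a
  self-loop would make descendant counts ill-defined. Parallel relations
  between the same pair (e.g. a binding *and* a regulation) are kept as
  attributes of one topological edge; all graph scores are topological, so
  multiplicity must not inflate them, but every relation record survives a
  round trip.
- **Directedness by type.** Binding is always symmetric; promoter binding
  and expression always carry a source→target arrow. Other types default to
  directed except chemical reactions and `unknown`. Direction and effect
  sign are preserved as attributes only — path-finding and scoring use the
  undirected view, since a walkable network must mix physical and
  regulatory edges.
- **Canonical relations.** Undirected relations store the lexicographically
  smaller endpoint first; duplicates of the canonical
  `(source, target, type)` triple are load errors. Canonicalisation is
  idempotent, so write→read→write is byte-stable.

File formats are SIF (`node relation node`), an attributed edge TSV
(`source, rel_type, effect, directed, target, references`), an expression
TSV (`gene_id, fold_change, p_value`), and GMT for gene sets. Node kind and
DE status cannot be expressed on an edge row, so the writers emit `#!node`
directive lines that the readers interpret and third-party tools skip as
comments; this also lets isolated nodes round-trip.

## DE screening

Up: fold change > 1.5 and p < 0.05. Down: fold change < 0.66 and p < 0.05.
All three comparisons are strict, so boundary records are never selected;
this is the only reading consistent with "greater than"/"less than"
threshold phrasing. Fold changes are used on the raw ratio scale — no log
transform — and no multiple-testing correction is applied at this stage:
the screen is a candidate filter, not an inference. When the same gene is
measured in several source tables, `deduplicate_records` keeps the record
with the smallest p-value (most-significant evidence); this is a documented
package choice, exposed separately from `select_de_genes` so callers can
substitute their own merge rule.

## Shortest-path network construction

For seed s and group G, let d\* = min over g ∈ G of the unweighted
shortest-path distance on the undirected view. If d\* ≤ `max_len`, **all**
shortest paths from s to **every** member at distance d\* are included. One
arbitrary path would make the output depend on adjacency ordering; taking
all tied paths is deterministic and matches the intent of connecting a seed
to the closest part of each group. A seed that is itself a group member is
at d\* = 0 and contributes only itself. Seeds with no group member within
`max_len` are logged and skipped, never fatal — real gene lists routinely
contain entities the interactome cannot connect.

`max_len` defaults to 4. There is no principled universal cap; 4 hops keeps
paths biologically interpretable (beyond that, almost everything in a
scale-free network is reachable and the construction dilutes to the whole
graph) and bounds runtime. The output is monotone in `max_len` by
construction.

Subtraction retains exactly the relations with at least one DE endpoint and
the nodes incident to them. It is idempotent, always an edge-subset of its
input, and tags retained nodes with their DE direction.

Summaries report the mean degree both as a real (2E/V) and truncated toward
zero, since the integer is the conventionally quoted figure (a 632-node,
2362-edge network has mean degree 7.47, quoted as "seven").

## Hub scoring

All five scores run on the undirected simple topology; disconnected graphs
are handled per component (a BFS tree spans only its root's component, and
cross-component pairs contribute nothing).

**BN.** The shortest-path tree is not unique, so the implementation pins a
deterministic tree: breadth-first layers, with each node's parent the
lexicographically smallest of its predecessors one level up. A node w with
strict-descendant count ≥ n/4 (real-valued, inclusive) in tree T_v is a
bottleneck of T_v; BN(w) counts qualifying roots. Two conventions:

- The root is excluded from its own tree's bottleneck count. Its descendant
  count is n − 1, which qualifies for every n, so including it would add a
  constant +1 to every node and carry no ranking information.
- The n/4 threshold is used as a real number with ≥ — no rounding.

The test suite checks BN against an independently written brute-force
oracle (explicit per-root layered BFS with the same parent rule, explicit
child-stack descendant counting) for exact equality on hundreds of random
graphs, and the planted-connector benchmark confirms that the top-BN node
is the designed articulation point whose removal partitions the graph.

**MNC / DMNC.** MNC(v) is the order of the largest connected component of
the subgraph induced by the open neighbourhood N(v); DMNC(v) divides that
component's edge count by its order raised to ε = 1.7. ε follows the
original definition of the score and is exposed as a parameter; a component
with ≤ 1 node scores 0 (it contains no edge, so no density is defined).

**DSS.** Stage 1 takes the top min(2n, |V|) nodes by DMNC; stage 2 re-ranks
the pool by MNC and outputs the top min(n, pool). The reported score is the
stage-2 MNC value. The factor 2 is the scheme's conventional empirical
choice and is configurable. Rationale for the combination: DMNC favours
nodes embedded in dense but not necessarily large modules, MNC favours
sheer neighbourhood size; the double screen keeps locally dense nodes that
a pure MNC ranking would flood with generic hubs, and vice versa.

All rankings order by descending score with ties broken by ascending node
id (DSS uses stage-1 DMNC as a secondary key first), making every table a
reproducible total order. Note that id tie-breaking means relabeling a
graph permutes tied nodes; order-preserving relabelings reproduce rankings
exactly.

## Over-representation

`p_raw = P(X ≥ k)` for X ~ Hypergeom(N, K, n), computed by the scipy
survival function at k − 1; the suite verifies agreement with exact
rational tail sums to 1e-12 up to N = 60. Only over-representation is
tested (one-sided). Correction is Benjamini–Hochberg by default — the
common default of enrichment tools — with Bonferroni as the alternative;
terms with zero study overlap are excluded from the report but still count
toward the correction denominator. The background defaults to the
annotation universe and is overridable; studies are silently restricted to
the background with a logged drop count.

## Synthetic-data generators

The generators emulate the shape of the real inputs, not their content:

- **Interactome**: Barabási–Albert preferential attachment, which
  reproduces the heavy-tailed degree distribution of curated interactomes
  (a few highly connected hubs over a sparse background). The edge count
  has the closed form m·(n − m) — the process starts from m isolated nodes
  and attaches each of the remaining n − m with m edges — which the tests
  assert. Relation types are sampled from a fixed weight table dominated by
  binding; the mix is plausible, not calibrated to any database.
- **Planted bottlenecks**: dense Erdős–Rényi clusters (p = 0.8, redrawn
  until connected) joined *only* through connector nodes, each wired to two
  anchors per cluster. Removing all connectors disconnects the graph by
  construction, and this is asserted on every instance.
- **Expression**: planted genes get fold change exactly 2.0 (up) or 0.5
  (down) with p ~ U(0, 0.01); nulls get log-uniform fold changes in
  [0.8, 1.25] with p ~ U(0, 1). Because the null band lies strictly inside
  the no-call region and planted p-values strictly below α, truth recovery
  by the screen is exact, not probabilistic — deliberately, so a recovery
  failure is always an implementation bug.
- **Annotations**: one planted term overlapping the target genes by a
  configurable fraction (default 1.0), padded to the term size with
  non-target genes, plus 50 null terms of size 10 sampled uniformly from
  the background.

Each generator draws from a single numpy `default_rng(seed)` stream in a
fixed documented order, so every artifact is bit-reproducible.

**What passing tests do not show.** Real microarray screens are noisy:
effects near thresholds, correlated probes, p-value miscalibration. The
exact-recovery property says nothing about screen behaviour under such
noise. Likewise the preferential-attachment null lacks the
literature-curation biases of real interactomes (well-studied proteins are
over-connected), so hub rankings on real networks partly reflect study
bias; and flat GMT terms ignore ontology structure (no true-path
propagation), so real GO enrichment with term nesting will differ.

## Pipeline and determinism

A run is configured by one YAML mapping with exactly one of a `simulate` or
`inputs` block — never both, so the provenance of every artifact is
unambiguous. Stages execute as screen → build → subtract → summarize → rank
→ enrich; in simulated runs the annotation terms double as the biological
groups for path construction, which keeps the synthetic study
self-contained. Any stage failure aborts with the stage name. The manifest
records the config snapshot, seed, SHA-256 digests and counts of every
artifact; identical configs and seeds yield identical digests because all
outputs are sorted and timestamp-free. Validation-suite problem sizes
(hundreds of nodes, tens of seeded replicates) were chosen so the whole
suite and the acceptance script each complete in seconds while still
exercising non-trivial graph structure.

## Known limitations

- Path construction is unweighted; no confidence-weighted shortest paths,
  Steiner trees or k-shortest-path variants.
- Hub scores carry no significance estimates; they are descriptive ranks.
- Group-to-group paths (no seed involved) are not added.
- The EPC (edge-percolated-component) score is out of scope.
- Fold-change orientation is taken as supplied; two-channel designs must be
  oriented before loading.
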