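# Methods

## Model and assumptions

`ppinet` treats the human interactome as an undirected graph whose nodes
are uppercase gene symbols and whose edges carry a confidence in [0, 1].
Three modelling assumptions run through the whole pipeline:

* **Topology over weight.** Edge confidences are used only as an optional
  parse-time filter (`min_confidence`, default 0.0 — keep everything);
  neither the shortest-path enrichment nor the propagation weights edges.
  The construction literature this pipeline follows describes filtering by
  protein identity and propagation "through the edges", so hop count is the
  only distance.
* **Guilt by association.** A protein adjacent to high-scoring proteins is
  itself a plausible candidate; propagation makes this quantitative by
  spreading seed scores along shortest paths with a 1/(d+1) decay.
* **Connectedness is required, not assumed.** Small secretome universes
  (~73 analytes) induce fragmented subgraphs; an explicit enrichment step
  adds the interior nodes of reference shortest paths until one component
  remains, because propagation cannot cross a component boundary.

## Pipeline stages

### Network construction

`build_case_network` composes three operations. `filter_by_universe` takes
the induced subgraph of the reference on the tissue universe.
`add_condition_neighbourhood` adds the condition's stimulus proteins and
their first reference neighbours, then closes over all reference edges
among the retained nodes (a PPI subnetwork conventionally keeps every known
interaction among its members). `enrich_connect` repeatedly merges the two
components whose closest node pair is at minimal unweighted reference
distance, adding the interior nodes of one shortest path per merge.
Neighbourhoods are added for the stimulus proteins only by default; a flag
(`include_seed_neighbourhood`) extends this to the dataset seeds.

Determinism where the mathematics is silent: component pairs are ordered
by (distance, lexicographically smallest sorted endpoint pair), and among
tied shortest paths the lexicographically smallest interior-node sequence
is taken (computed greedily against a reverse-BFS distance map). One path
per merge keeps the added node count minimal in spirit; a Steiner-optimal
connection is deliberately out of scope. If the reference itself cannot
connect the nodes the partial result is returned with `connected=False`
and a warning rather than an exception, so a fragmented universe still
produces a usable report.

Induced subgraphs are always rebuilt node-by-node in sorted order. This
makes every downstream iteration order — score sums, Louvain's seeded
shuffle — independent of Python's per-process hash randomization, which is
what makes whole runs bit-reproducible.

### Seed scoring

Secretome cases: replicate concentrations (nominally pg/ml) are averaged
arithmetically, min–max scaled over the *measured panel* (not over network
nodes — scaling happens before restriction, so network composition cannot
change an analyte's score), unmeasured network nodes score 0, and each
stimulating cytokine is overwritten to 1.0, the score of the most expressed
protein. Mass-spectrometry cases are binary: curated seeds and stimuli
score 1, everything else 0. Degenerate panels (all values equal) scale to
all-zeros with a warning instead of dividing by zero. A stimulus missing
from the network is an error by design: it indicates the network was built
without the condition's proteins.

### Propagation

The score update per repetition is

    s'(u) = (1/|O(u)|) · Σ_{o ∈ O(u)} s(o) / (d(u,o) + 1)

with `O(u)` the nodes within `n_iterations` hops of `u` (including `u` at
`d = 0`), followed by division of the whole vector by its maximum
(`normalize_each_repetition`, default on). Defaults `n_repetitions = 3`,
`n_iterations = 2` follow the GUILD reference implementation's NetScore
defaults. The concrete decay (1/(d+1)), self-inclusion, mean aggregation
and max-normalisation are this package's fully specified variant of the
scheme; all four are exposed in `PropagationConfig` or the function
surface, and the tests pin the implementation to an independent
message-enumeration oracle at 1e-12. Two consequences worth knowing:
scores are strictly local (a node farther than `n_repetitions ×
n_iterations` hops from every seed ends at exactly 0), and ranking — not
the absolute score — is the meaningful output.

Ranking sorts by descending score with lexicographic tie-breaks, so ranks
are distinct and reproducible.

### Prioritization

`select_top` takes the first `⌊k/100 · N⌋` nodes of the ranking — floor,
never round, so candidate counts are stable and nested
(`top 2 % ⊆ top 5 %`). When proteins are excluded first (e.g. dropping the
stimuli via the `exclude` flag), the floor applies to the remaining rows.
Stimuli are *not* excluded by default: a stimulated condition legitimately
prioritizes its stimulus. `compare_conditions` computes the intersection
(shared) and each condition's top set minus the union of the others
(unique); the pipeline's default contrasts compare each stimulated
condition pairwise against its network's no-treatment baseline, which makes
"unique" mean "unique versus baseline"; `unique_vs: all` switches to joint
comparison across all sibling conditions.

### Network metrics

Average degree `2E/N`, per-node clustering with `C_i = 0` for degree < 2
averaged over *all* N nodes, density `2E/N(N−1)`, Newman–Girvan modularity
maximised by the seeded two-phase Louvain heuristic, and diameter read as
the longest shortest path (the graph-theoretic diameter; a literal longest
simple path would be NP-hard and is clearly not what a network summary
table means). Disconnected graphs report the diameter of the largest
component with a warning. Louvain's node visit order is shuffled by an
explicit `rng_seed`, so reported Q values are reproducible; Q of a
single-community partition is identically 0, which bounds Louvain's result
from below.

## Synthetic data: what it emulates, and what it does not

The generator produces planted-partition (stochastic block model)
interactomes — near-equal communities, within-community edge probability
`p_in`, between-community `p_out`, confidences uniform on [0.5, 1] — with
one community designated the disease module and a configurable number of
true seeds drawn from it. Defaults (400 nodes, 4 communities, `p_in` 0.3,
`p_out` 0.01, 5 seeds) give dense, well-separated modules whose recovery by
propagation is the pipeline's end-to-end benchmark: in 40 independently
seeded runs the top-5 % candidate set should exceed the module's 0.25
background share essentially always. Secretome panels are 73 analytes ×
3 replicates of log-normal concentrations (location log 100, scale 1.5 —
multiplex immunoassay panels are strongly right-skewed and span decades),
with multiplicative per-protein condition effects and log-normal replicate
noise (σ = 0.2). MS universes are identifier sets of exact requested size
(default 14,000) containing any required seed panel.

What passing on synthetic data does **not** show: real interactomes are
scale-free-ish with strong literature bias (well-studied proteins have
inflated degree), not block-structured; real secretome panels share batch
effects across analytes; and real universes carry identifier ambiguity that
the uppercase-symbol convention only papers over. A degree-corrected
generator variant would narrow the first gap and is left as future work.

## Numerical and interface choices

* Duplicate edge-list rows (either orientation) keep the **maximum**
  confidence — conservative retention of the stronger evidence.
* Self-loops are dropped at parse time; malformed rows are rejected and
  counted, never fatal; an all-filtered file yields an empty interactome
  plus a warning.
* Identifiers are case-folded to uppercase symbols; database-native IDs go
  through an explicit two-column IdMap, and unmappable rows are dropped.
* Isolated nodes survive edge-list round-trips via `#node` records, so
  write→read is the identity on (nodes, edges, confidences).
* All-zero initial score vectors propagate to all-zeros with a warning
  (nothing to rank) rather than erroring, keeping batch runs total.
* The problem sizes used by the test suite and the acceptance script
  (≤ 400-node benchmarks, 40 recovery runs, ≤ 30-node metric oracles,
  ≤ 12-node propagation oracles, ≤ 8-node exhaustive Louvain checks) were
  chosen so every oracle is exactly computable while the planted-module
  benchmark still has unambiguous community structure.

## Known limitations

* The propagation variant is specified by this package, not byte-compatible
  with the original GUILD binary; rank-level agreement is the intended
  validation surface, and absolute scores should not be compared across
  implementations.
* `enrich_connect` recomputes component-pair distances per merge; fine for
  the hundreds-to-thousands-of-nodes networks this pipeline targets, not
  tuned for full-interactome-scale enrichment.
* Modularity and the other metrics are unweighted by design; weighted
  variants are intentionally absent.
* Category profiles report raw composition only — no enrichment statistics
  are attached to candidate categories.
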