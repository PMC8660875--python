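# Methods

## The estimation model

A group's semantic network is estimated from category fluency lists in four
steps.

**Response matrix.** After normalisation (Unicode casefold, NFKD accent
stripping, whitespace collapsing, then a table-driven variant→canonical map
and optional category lexicon), each group's lists become a binary
participants × exemplars matrix; production order is kept in the records but
plays no role downstream. Normalisation is table-driven rather than
stemmer-based: a table is auditable and language-neutral, and fluency studies
typically merge only a handful of root variants. Accent stripping is part of
canonicalisation because the intended use includes French-language data, where
"léopard"/"leopard" must merge.

**Minimum occurrence and equating.** Exemplars produced by fewer than
`min_count = 2` participants in a group are dropped *per group*, then both
groups are restricted to their shared exemplar set. The order matters and is
fixed: filter first, equate second. Equal node sets (and, after TMFG, equal
edge counts) mean a group difference in a measure cannot be an artifact of
network size.

**Cosine association.** `A_ij = c_ij / sqrt(f_i · f_j)` with `c_ij` the
number of participants producing both exemplars and `f_i` the column sum.
Values lie in [0, 1]; the diagonal is stored as zero and never used, since
self-similarity carries no edge information.

**TMFG.** The triangulated maximally filtered graph keeps `3n − 6` edges:
seed the four nodes with the greatest total association as a K4, maintain the
list of triangular faces, and repeatedly insert the unplaced node `v` into
the face `{a, b, c}` maximising `w(v,a) + w(v,b) + w(v,c)`, replacing that
face with three new ones. Ties break toward the lexicographically smallest
node label, then the earliest-created face, so estimation is fully
deterministic. The construction guarantees planarity, connectedness, minimum
degree 3 and membership of every node in a triangle; the implementation
asserts the edge-count law and the test suite checks the greedy choice
against an exhaustive (node × face) scan at small n. The seed rule
(max-total-association K4) is the standard greedy formulation; other seedings
exist, and nothing downstream depends on which is used beyond determinism.

## Network measures

All three measures are computed on the **unweighted** graph by default: path
length is defined in steps (edges), and using one convention for CC, ASPL
and Q keeps them commensurate. `weighted=True` switches to the
networkx weighted clustering (geometric-mean edge intensity) and
inverse-weight shortest paths for sensitivity analysis; this weighted CC is
the Onnela intensity variant rather than Barrat's, because it is the form
networkx provides and the flag exists for robustness checks, not inference.

- **CC** — mean Watts–Strogatz local clustering; degree-<2 nodes contribute 0
  (cannot occur on TMFG output).
- **ASPL** — mean hop distance over unordered pairs, BFS per node;
  disconnected input is an error at this level (TMFG output is always
  connected; null-model code handles its own disconnected draws).
- **Q** — Newman–Girvan modularity of the best partition found by Louvain
  (igraph's multilevel implementation) over `restarts` seeded restarts, each
  with a permuted vertex order; the best-Q partition is reported, matching
  the usual single-summary practice. Resolution is fixed at 1. With 100
  restarts on ~100-node TMFG graphs, best-of-restarts Q matches exhaustive
  partition search at small n and is stable to the third decimal at study
  scale.

## Inference

**Random-graph nulls.** "Same nodes and edges" is realised as `G(n, p)` with
`p = m / C(n, 2)` — an ensemble with a *fixed edge probability* whose
expected edge count is `m`; `model="gnm"` gives the exactly-`m` variant. ASPL
of a disconnected draw is computed on the largest component, the standard
convention that keeps the statistic finite. The empirical value is located in
the null distribution with a two-sided add-one percentile p,
`p = 2·(1 + min(#≤, #≥)) / (iters + 1)`, capped at 1, so p is never zero and
the attainable floor with 1000 draws is 2/1001 ≈ 0.002; the report prints
this floor (claiming p < 0.001 requires ≥ 1999 draws).

**Case-wise bootstrap.** Each iteration resamples each group's participants
with replacement to the original group size and re-runs the *full* chain —
filter, equate, cosine, TMFG, measures. Equating is re-applied inside every
iteration (the fully case-wise reading); `equate_each_iteration=False` fixes
the node set from the full sample instead, dropping exemplars a resample
never produced. Resamples that cannot support estimation (fewer than four
shared exemplars) are redrawn with the count logged, so distributions keep
length `iters`. Seeding: per-iteration, per-attempt, per-group substreams
derived from the master seed (the group enters via a stable label hash), so
runs are reproducible and two identical groups produce identical
distributions. Distributions are compared with pooled-variance Student t
tests (`df = n_a + n_b − 2`; 1998 for two 1000-iteration runs) and
pooled-SD Cohen's d that carries the sign of the mean difference. The t test
on bootstrap replicates treats iterations as observations; its df reflect
the number of resamples, not participants, which is a known overstatement of
certainty inherited from the procedure itself — effect sizes are the more
interpretable output.

**Behavioral statistics.** The t test accepts raw vectors or mean/SD/n
summaries (published tables rarely come with raw data; pooled-variance
results are identical either way). With raw vectors, a median-centred Levene
test auto-selects Welch at p < 0.05. The 2×2 chi-square is Pearson's
*without* continuity correction, with φ = sqrt(χ²/N). Effect-size labels use
the 0.20/0.50/0.80 benchmarks.

## The synthetic cohort generator

The generator exists because raw transcripts for this kind of developmental
cohort are typically not shareable; it gives every pipeline stage a
ground-truth target.

- **Ground truth** — a planted-partition (stochastic block model) graph:
  `n_concepts = 120` concepts in `n_modules = 6` equal modules, within-module
  edge probability `p_in = 0.35`, between-module `p_out` as the modularity
  dial. Modules emulate semantic subcategories (farm animals, birds, …).
  Disconnected draws are rejected and redrawn with a bounded budget.
- **Fluency lists** — a censored random walk, the standard generative account
  of fluency: uniform start, uniform neighbour steps, uniform restart with
  probability `jump_prob = 0.05`, and a concept emitted only on first visit,
  which guarantees duplicate-free lists and hence binary matrices. The target
  list length is truncated-normal on [1, n_concepts]; a step cap of 50× the
  target bounds runtime and is logged when hit.
- **Study-scale defaults** (`study_cohort`) — groups of 36 and 31
  participants with list-length means/SDs of 16.4/5.0 and 14.8/5.8, one
  shared 120-concept label universe, and `p_out = 0.08` (group A, less
  modular) vs `0.02` (group B, more modular). The walk-length distribution is
  matched to the target scale so vocabulary overlap between groups is
  realistic.

What the generator does **not** emulate: real production frequencies are
strongly Zipfian (everyone says "cat"; one child says "axolotl"), whereas
walk visit rates over a planted-partition graph are comparatively uniform.
At 36 participants the walks therefore nearly saturate the 120-concept
universe (~115 distinct exemplars per group rather than the ~90–105 a real
cohort of this size shows), and the equated networks come out around
95–100 nodes rather than ~68. Passing tests consequently demonstrate
pipeline correctness and direction-of-effect recovery under a known ground
truth, not that empirical measure *magnitudes* (CC ≈ 0.70, ASPL ≈ 3.1,
Q ≈ 0.59) will be reproduced on real data. There is no response-time
structure, no age or covariate simulation, and no semantic-space geometry.

## Numerical and design notes

- Column ordering of response matrices is lexicographic; all tie-breaks in
  TMFG are explicit; Louvain restarts are seeded — identical inputs and
  seeds give byte-identical outputs, including GraphML and CSV exports.
- "Unique responses the other group did not provide" is operationalised as
  the set difference of produced-exemplar sets; other readings (e.g.
  counting tokens) exist, and the choice is documented rather than asserted.
- Problem sizes in the test suite (bootstrap iterations of 200 in the
  recovery study, null ensembles of 1000, 20 generator seeds) were chosen so
  the full suite runs in a few minutes on one CPU while keeping Monte Carlo
  error far below the effect sizes being detected; production analyses
  should use the 1000-iteration defaults.
- Known limitations: group-level networks cannot support individual-level
  correlations with behavior; bootstrap-t df inflation (above); the
  unweighted-measure convention is a choice, with the weighted variants
  provided precisely because the convention is not empirically forced.
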