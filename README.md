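# fluencynet

Group-level semantic network analysis of category verbal-fluency data.

Verbal fluency tasks ("name as many animals as you can in 60 seconds") are a
classic window into how concepts are organised in semantic memory. When two
groups of speakers — for example schoolchildren from different educational
backgrounds — are compared, the question is not only *how many* exemplars each
group produces, but how the produced exemplars hang together. `fluencynet`
implements the group-level network approach to that question, for researchers
in cognitive network science and psycholinguistics:

1. **Preprocessing** — transcripts are canonicalised (case folding, accent
   stripping, table-driven variant merging, optional category lexicon),
   deduplicated, and tabulated into binary participants × exemplars response
   matrices.
2. **Network estimation** — exemplars produced by fewer than two participants
   in a group are dropped, both groups are equated onto their shared exemplar
   set, a cosine association matrix is computed
   (`A_ij = c_ij / √(f_i f_j)`, with `c_ij` the co-production count and `f_i`
   the production frequency), and the **triangulated maximally filtered graph
   (TMFG)** retains the `3n − 6` strongest associations in a planar,
   connected network — the same edge count for both groups, so structural
   comparisons are not confounded by density.
3. **Network measures** — the clustering coefficient (CC), average shortest
   path length (ASPL), and modularity (Q, best-of-restarts Louvain), computed
   on the unweighted graph.
4. **Inference** — each empirical measure is compared against an
   Erdős–Rényi `G(n, p)` ensemble with matched nodes and edges (two-sided
   add-one percentile p), and group differences are tested by **case-wise
   bootstrap**: participants are resampled with replacement, the full
   estimation chain is re-run per iteration, and the resulting measure
   distributions are compared with pooled-variance t tests and Cohen's d.
5. **Behavioral statistics** — independent/Welch t tests (from raw vectors
   *or* published mean/SD/n summaries), 2×2 chi-square with φ, and Pearson
   correlations for the accompanying demographic/fluency/creativity tables.

Because raw fluency transcripts from developmental studies are rarely public,
the package ships a **synthetic cohort generator**: each group's semantic
memory is a planted-partition graph over a shared concept universe, and each
participant's list is a censored random walk over it. The generator's
between-module edge probability is a ground-truth modularity dial, which makes
the whole pipeline testable for parameter recovery.

## Worked example

```python
import fluencynet as fn

# Two synthetic groups at study scale: group A (36 children) walks a less
# modular ground truth than group B (31 children).
rec_a, rec_b, _, _ = fn.study_cohort(0)
mat_a = fn.build_response_matrix(rec_a)
mat_b = fn.build_response_matrix(rec_b)

eq_a, eq_b = fn.equate_nodes(
    fn.filter_min_occurrence(mat_a), fn.filter_min_occurrence(mat_b)
)
for mat in (eq_a, eq_b):
    net = fn.tmfg_filter(fn.cosine_association(mat), group=mat.group)
    m = fn.compute_metrics(net, seed=0, restarts=100)
    print(mat.group, f"n={m.n_nodes} m={m.n_edges} "
          f"CC={m.cc:.3f} ASPL={m.aspl:.3f} Q={m.q:.3f}")

boot = fn.casewise_bootstrap(mat_a, mat_b, iters=200, seed=0)
for c in fn.compare_groups(boot):
    print(f"{c.measure:>4}: t({c.df}) = {c.t:.2f}, p = {c.p:.2g}, "
          f"d = {c.d:.2f} ({c.effect_label})")
```

prints

```
A n=99 m=291 CC=0.706 ASPL=3.779 Q=0.691
B n=99 m=291 CC=0.700 ASPL=4.187 Q=0.689
  cc: t(398) = 4.53, p = 7.8e-06, d = 0.45 (small)
aspl: t(398) = -7.40, p = 7.9e-13, d = -0.74 (moderate)
   q: t(398) = -5.45, p = 8.6e-08, d = -0.55 (moderate)
```

Both groups' networks share 99 nodes and, by the TMFG edge law, exactly
`3·99 − 6 = 291` edges. The bootstrap comparison recovers the planted
contrast: the group walking the less modular semantic graph shows higher
clustering, shorter paths, and lower modularity — the "flexible network"
signature. Positive `t`/`d` mean group A exceeds group B; effect labels
follow the 0.20/0.50/0.80 small/moderate/large benchmarks.

The same analysis runs from the shell:

```bash
fluencynet simulate --seed 0 --out cohort.csv
fluencynet run-all --transcripts cohort.csv --seed 0 --out-dir results/
```

which writes per-group GraphML networks, metric and null-model JSON reports,
the bootstrap CSV, the comparison report, and a run log with every seed.

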