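# cogtypology

Graph-based cognitive typology for neuropsychological cohorts.

Cognitive aging is heterogeneous: some older adults perform like young
adults, some young adults look "old", and group averages hide both.
`cogtypology` derives a *typology* — data-driven subgroups of
participants with similar cognitive profiles — from a standard
neuropsychological test battery, without splitting the cohort by age
beforehand. It is written for researchers in aging, neuropsychology and
biostatistics who want the full chain as a tested, reusable library:

1. **Compound scores.** Raw test scores (letter/semantic fluency counts,
   digit spans, trail-making times, 15-words recall, median reaction
   time) are reduced to 8 compound scores, z-transformed over the cohort
   and oriented so higher = better (the three time-based scores are
   multiplied by −1).
2. **Similarity graph.** Every pair of participants *i, j* gets an
   intraclass correlation ICC(A,1) — two-way model, absolute agreement,
   single measures — over their 8-score profiles:
   `ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))`
   with *n* = 8 scores as rows and *k* = 2 participants as columns. The
   matrix is thresholded at the largest *t\** that keeps the graph
   connected (reachability 1) — the bottleneck edge of a maximum
   spanning tree.
3. **Community detection.** Spectral modularity maximization: recursive
   bisection along the leading eigenvector of the modularity matrix
   `B = A − k kᵀ/2m`, Kernighan–Lin fine-tuning of every split, exact
   sub-split gains via the generalized matrix `B(g)`, stopping when no
   split increases `Q = (1/2m) Σᵢⱼ Bᵢⱼ δ(cᵢ,cⱼ)`.
4. **Stability validation.** An RBF-kernel SVM is trained on the same 8
   z-scores with the detected community as label, under leave-one-out
   and stratified half-split cross-validation; per-subgroup sensitivity
   (TP / subgroup size) and specificity (TN / non-members) quantify how
   reliably a new individual would be classified.
5. **Profile report.** Per-subgroup five-number summaries of the
   oriented z-scores, plus covariate tests that never entered the
   clustering: one-way ANOVA with Holm-adjusted pairwise comparisons for
   MMSE, HADS, IQ estimates and digit-symbol coding, and pairwise
   Pearson chi-squares for education level.

Because cohorts of this kind are rarely shareable, the package ships a
**synthetic-cohort generator** (`cogtypology.simulate`) that plants six
subgroups with realistic sizes (23/39/31/26/11/25), distinct mean
profiles, Gaussian within-subgroup noise and subgroup-linked covariates,
and emits raw-score tables in the same CSV schema the pipeline reads —
so every stage is testable end to end against known ground truth.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from cogtypology import (Graph, apply_inclusion, apply_threshold, build_icc_matrix,
                         compound_scores, default_spec, detect_communities, generate,
                         max_connected_threshold, standardize_and_orient)

table, truth = generate(default_spec(seed=0))     # 155 synthetic participants
included, _ = apply_inclusion(table)              # MMSE > 26, HADS subscales < 16
cm = standardize_and_orient(compound_scores(included))
sim = build_icc_matrix(cm)                        # 155 x 155 ICC(A,1)
t_star = max_connected_threshold(sim)
part = detect_communities(Graph(apply_threshold(sim, t_star).adjacency))
print(t_star, part.n_communities, round(part.q, 3), part.community_sizes())
print(round(adjusted_rand_score(truth.to_numpy(), part.labels), 3))
```

prints

```
0.5363411253526309 6 0.699 [23, 39, 30, 26, 26, 11]
0.984
```

i.e. the sparsest connected graph forms at ICC ≥ 0.536; modularity
maximization finds 6 communities at Q = 0.699 whose sizes match the six
planted subgroups almost exactly (adjusted Rand index 0.984 — one
borderline participant swapped). The scripts in `examples/` walk through
each stage the same way (`05_validate_stability.py` runs the full LOOCV
and takes a few minutes; everything else is seconds).

A one-command version of the whole analysis, with every intermediate
artifact written to disk, is available as a CLI:

```bash
cogtypology run --seed 0 --out results/        # default synthetic cohort
cogtypology run --input my_cohort.csv --out results/
```

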