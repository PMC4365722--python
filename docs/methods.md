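# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cogtypology`, in the order the pipeline runs them.

## Cohort schema and inclusion screening

A cohort is one row per participant with raw test scores and covariates
(`cogtypology.cohort.RAW_COLUMNS`). The inclusion screen retains
participants with MMSE > 26 and both HADS subscales < 16, read as strict
inequalities; `mmse_inclusive` / `hads_inclusive` flags relax the
boundaries to ≥ / ≤ for cohorts screened with the other convention.
Participants missing any score that feeds a compound are dropped with a
logged reason ("did not complete all neuropsychological tests") — the
missing-data policy is listwise deletion, never imputation, because the
similarity measure needs complete 8-score profiles.

## Compound scores, standardization, orientation

The eight compound scores: phonemic fluency = mean(S, F word counts);
semantic fluency = mean(professions, animals); working-memory span =
mean(digit span forward, backward); trail-making A time (s); trail-making
B/A time ratio (an executive-function index less confounded by raw
speed); immediate recall = sum of the five 15-words blocks; delayed
recall; response speed = median RT (ms). The 15-words recognition score
is deliberately excluded: near-ceiling performance in healthy adults
makes it uninformative for a typology. Compounds are computed first and
z-transformed second (matching the definition of the B/A ratio as a
ratio of raw times).

z-scores are pooled over the whole included cohort — young and old
together, since the typology is meant to emerge without an a-priori age
split — using the sample SD (ddof = 1, exposed as config; the choice is
immaterial at n = 155, ~0.3% on every z). After standardization the
three time-based columns (TMT-A, TMT-B/A, RT) are multiplied by −1 so
that a higher oriented score always means better performance; these are
exactly the scores where a higher raw value is worse.

## Pairwise ICC(A,1) similarity

Similarity between two participants is ICC(A,1): two-way model, absolute
agreement, single measures, computed on the n = 8 × k = 2 table with
scores as rows. Absolute agreement is the point — a participant whose
profile has the same shape but a constant offset is *less* similar than
an identical profile, which a Pearson correlation would miss. ICC is
computed on the *oriented* z-scores: sign flips change pairwise ICC
materially, and orientation makes "agreement" mean agreement in
performance quality rather than in raw time/count units.

A pair of exactly equal constant profiles has a 0/0 ICC; the package
raises a dedicated error (tolerance 1e-12 on the denominator) rather
than guessing. `build_icc_matrix` is a vectorized implementation that is
tested to equal the scalar `icc_a1_pair` on every pair to 1e-10, and
`icc_a1_pair` itself is tested against a naive two-way ANOVA oracle and
against `pingouin.intraclass_corr`'s ICC(A,1) row.

## Threshold selection and the binary graph

The similarity matrix is binarized with the closed rule `edge iff
ICC ≥ t`, so the chosen threshold is attained by an actual edge. The
canonical threshold t* is the largest value at which the graph remains
connected (reachability 1, i.e. every participant reaches every other);
it equals the minimum-weight edge of a maximum spanning tree, which is
how it is computed (networkx, Kruskal). Ties among equal ICC values are
all kept by the closed rule. The adjacency passed to community detection
is binary; an ICC-weighted variant would be a straightforward extension
(weights for A, strengths for degrees) but the default mirrors the
thresholding construction. Self-edges are excluded throughout.

Reachability is reported as the fraction of ordered node pairs connected
by a path; it is non-increasing in t (property-tested).

## Spectral modularity maximization

Communities maximize Newman–Girvan modularity
Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j) by recursive spectral
bisection:

* **Split proposal.** Leading eigenpair of the modularity matrix B (or
  the generalized B(g) = B restricted to subset g with the diagonal
  re-centered so rows again sum to zero) via dense symmetric
  eigendecomposition (`numpy.linalg.eigh` — deterministic, no random
  initialization; fine up to a few hundred nodes). s_i = +1 where the
  eigenvector component is positive; components within 1e-12 of zero get
  +1 for determinism (fine-tuning can correct them). The eigenvector's
  arbitrary global sign is canonicalized by making its largest-magnitude
  component positive.
* **Indivisibility.** A subset whose B(g) has no eigenvalue above
  `eigen_tol` (default 1e-10) is left whole.
* **Fine-tuning.** Kernighan–Lin-style sweeps after *every* bisection:
  each vertex is flipped at most once per sweep, always the flip with
  the largest ΔQ gain (gain of flipping i is (B_ii − s_i (Bs)_i)/m,
  updated incrementally; ties go to the lowest index), the best
  intermediate state of the sweep is kept, and sweeps repeat until the
  improvement is ≤ `fine_tune_tol` (default 1e-12). ΔQ never decreases
  (property-tested over random starts).
* **Acceptance.** A split is kept only if ΔQ = sᵀB(g)s/4m > 0, so the
  final Q is strictly the sum of accepted gains and never below the
  trivial partition's Q = 0. The recomputed Q from the final labels must
  agree with the accumulated gains (guard at 1e-9).

On random connected graphs with ≤ 8 nodes the algorithm attains the
exhaustive-search maximum Q in well over 90% of cases (tested against a
Bell-number enumeration of all partitions); spectral bisection is a
heuristic and the occasional shortfall is recorded, not hidden.
Disconnected input is rejected with a pointer to re-select the
threshold. `threshold_robustness` re-partitions at alternative
thresholds and flags community-count instability.

## Stability validation (RBF-SVM)

Features are exactly the clustering features (the 8 oriented z-scores);
labels are the detected communities. The classifier is a multi-class
RBF-kernel SVM (scikit-learn SVC, one-vs-one). Hyperparameters C and γ
are selected by an inner stratified 5-fold grid search on the training
data only, over the logarithmic grid C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
with exponent step 2 (the classic LIBSVM grid-search default step),
seeded and deterministic; fixed values can be passed instead. If the
smallest training class has < 5 members the inner CV degenerates to
fewer folds, and a singleton class skips the search (logged warning,
mid-grid defaults).

Two schemes: leave-one-out CV (n rounds, each participant predicted once
from a model trained on the rest, hyperparameters re-selected per round)
and data partitioning (each class of size s contributes ⌈s/2⌉ members to
training and ⌊s/2⌋ to testing, randomly within class given the seed; a
single split, not averaged, with the larger half training). Per class,
sensitivity = TP / true class size and specificity = TN / number of
evaluated non-members, in percent; both are tested to agree exactly with
brute-force counting over prediction/label pairs. LOOCV is known to be
optimistic relative to half-splitting at small n; the package reports
both rather than asserting an ordering.

## Profile report

Per-community five-number summaries (min, Q1, median, Q3, max) of the
oriented z-scores use linear-interpolation quartiles (numpy default,
type-7), with scores ordered by increasing median — the conventional
way subgroup boxplot panels are arranged. Young/old counts come from the
age-group column, which never enters the clustering.

Covariate tests: classical one-way ANOVA (F = MS_between/MS_within, p
from the F distribution) per continuous covariate over communities,
followed by all pairwise comparisons — Welch t with Holm step-down
adjustment by default (the omnibus report does not name a post-hoc
procedure convention, so a robust default with a Tukey HSD alternative
is exposed), signed row-vs-column. Education level (ordered categories
1–4) is compared per community pair with a Pearson chi-square on the
2 × L contingency table, no continuity correction, all-zero levels
dropped (reducing df), and expected counts < 5 flagged. The default
covariate list is MMSE, HADS anxiety/depression, crystallized and fluid
IQ, and digit-symbol coding; it is configurable.

## Synthetic cohorts

The generator plants six subgroups with default sizes
(23/39/31/26/11/25, total 155), age compositions, and covariate
(mean, sd) pairs emulating a realistic mixed cohort of 79 young and 76
older adults. Mean cognitive profiles are 8-vectors in oriented
population z-units; their *sign structure* encodes the qualitative
subgroup descriptions (S1: weak fluency, strong elsewhere; S2: strong
executive/memory, weaker fluency/span/RT; S3: slow but otherwise strong;
S4: fast but otherwise weak; S5: globally weak, worst on the B/A
executive index; S6: weak memory and RT, otherwise strong). The
magnitudes were calibrated once against the planted-partition recovery
property and then frozen; two lessons from that calibration are worth
recording. First, a *flat* profile (low variance across the 8 scores)
gives low ICC even between members of the same subgroup — ICC(A,1)
needs row variance — so every planted profile keeps a score variance
near 1 z². Second, subgroups with shape-correlated profiles merge under
modularity's resolution limit even when they are far apart in Euclidean
distance, so the closest pairs were decorrelated in shape. The
`separation` parameter scales all profiles linearly; 2.0 is the
calibrated default.

Per member, the 8 oriented z-scores are drawn independently as
Normal(profile mean, within_sd²) with within_sd = 0.6 z-units by default
(chosen so profiles overlap yet remain recoverable; a correlation
structure between scores is a config hook, not a default, since no
within-subgroup covariance information is available to emulate). The
z-draws are mapped to raw units via per-score anchors (e.g. phonemic
fluency 16 ± 4 words, TMT-A 35 ∓ 10 s — time-based anchors map with a
negated slope) and the compound definitions are inverted to emit raw
fields: fluency and span pairs are split around an integer total so the
compound mean is preserved exactly, the five recall blocks sum exactly
to the drawn total with a rising-with-practice shape, TMT-B is the drawn
ratio times the drawn TMT-A. Values outside physical ranges (negative
times or counts, recall blocks > 15 words) are clipped and the clip
count logged. Covariates are drawn per subgroup from the default
(mean, sd) defaults, with MMSE clipped into [27, 30] and HADS into [0, 15]
so the generated cohort represents the *included* population the
demographics describe. Generation is a pure function of the spec's seed.

What the generator does **not** emulate: item-level responses,
within-person score correlations, longitudinal change, non-Gaussian
tails, and real-world missingness. Passing recovery tests therefore
show that the pipeline can find subgroup structure of the planted kind
at realistic sizes and noise — not that any particular real cohort has
such structure. On synthetic cohorts the connectivity threshold lands
near 0.55 and Q near 0.7; real cohorts are messier, with thresholds
nearer 0.4 and Q nearer 0.5 typical for analyses of this design.

## Problem sizes and determinism

Default test-suite sizes: 1000 random tables for the ICC oracle, 200
matrices (P ≤ 30) for the threshold oracle, 200 connected graphs
(P ≤ 8) against exhaustive modularity search, 100 random starts per
graph for fine-tuning monotonicity, 50 seeds of the full 155-participant
pipeline for planted-partition recovery, with threshold-robustness
sweeps at {t*, t*−0.05, t*−0.10}. The whole pipeline is deterministic
given its config and a single global seed, fanned out to per-stage seeds
by fixed offsets; hypothesis-based property tests run derandomized.

## Known limitations

* Spectral bisection with fine-tuning is a heuristic; it can miss the
  global optimum (observed rarely on small graphs) and inherits
  modularity's resolution limit — small genuine subgroups (~10 members)
  can merge into larger ones in dense graphs, which is also the main
  source of the residual community-count instability at thresholds well
  below t*.
* t* is a bottleneck statistic: a single outlier participant with weak
  similarity to everyone drags the threshold down for the whole graph.
* LOOCV re-selects hyperparameters every round, which is honest but
  slow (minutes at n = 155 with the default grid); pass `fixed_params`
  or a coarser grid for interactive use.
* The half-split scheme is a single random partition by design; repeated
  averaging would reduce variance but no longer mirror the reported
  procedure. A config flag for repeated splits is a planned extension.
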