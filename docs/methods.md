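# Methods

## The mixed-type distance

Questionnaire cohorts mix 4-level ordinal symptom items with continuous
psychological totals, and no single textbook metric treats both while using
the dependence *between* attributes. The metric here is assembled from four
ingredients, each estimated from the analyzed table only.

**Intra-attribute ordinal term.** The distance between levels *a* and *b*
of ordinal variable *j* is `|F_mid(a) − F_mid(b)|`, where
`F_mid(c) = P(X_j ≤ c) − p_j(c)/2` is the midpoint CDF. This respects the
level order, is additive along it, and shrinks the gap across rarely used
levels. Marginals are unsmoothed, so a uniform 4-level variable gives
exactly 0.75 between the extreme levels.

**Inter-attribute ordinal term.** Levels *a* and *b* of *j* also differ to
the extent that they predict different distributions for the other
variables: for each context variable *k*,
`φ_jk(a,b)² = JSD(P(·|X_j=a), P(·|X_j=b)) / ln 2`, the Jensen–Shannon
divergence between the conditional distributions over *k*'s levels
(ordinal) or over *B* = 8 equal-frequency bins (continuous). Conditional
tables receive additive smoothing α = 0.5 per cell so the divergences never
see artificial zeros. Context terms are weighted by normalized mutual
information, `w_jk = NMI(j,k)/Σ_{k'≠j} NMI(j,k')` with
`NMI = I/√(H_j H_k)`, so unrelated contexts are discounted. The full level
distance is `d_j(a,b)² = δ_intra(a,b)² + Σ_{k≠j} w_jk φ_jk(a,b)²`.

**Numeric block.** Continuous variables use a shrinkage Mahalanobis
distance with `S_λ = (1−λ)S + λ diag(S)` (λ = 0.1), which keeps the block
invariant to per-variable rescaling while regularizing the inverse. The
correlation structure among the psychological scores is carried entirely by
this block; inter-attribute information flows only into the ordinal level
distances. Whether numeric attributes should also receive
categorical-context terms is left open; the asymmetry follows the division
of labour between the two blocks.

**Block balance.** The squared distance is
`D² = s_ord Σ_j d_j² + s_num d_num²`, with the scales chosen so each
block's mean squared off-diagonal contribution equals its attribute-count
fraction (30/38 ordinal, 8/38 numeric on the default schema; the numeric
block is absent in GI-only mode). Equal-per-attribute influence is the
least-informative prior; it is also the main tunable lever if one block is
known to matter more. The result is symmetric, non-negative, and zero on
identical records; the triangle inequality is not claimed, and spectral
clustering does not need it.

## Spectral clustering

Affinities use local scaling, `W_xy = exp(−D²_xy/(σ_x σ_y))` with `σ_x` the
distance to the 7th nearest neighbour (m = 7 default; zero σ falls back to
the smallest positive one). Labels come from k-means (greedy k-means++
seeding, 20 restarts, best inertia) on the row-normalized eigenvectors of
the k smallest eigenvalues of `L_sym = I − D^{−1/2} W D^{−1/2}`. Isolated
vertices abort with their positions named. Per-cluster compactness is the
mean within-cluster distance in the *original* metric, not the embedding.

## Choosing k: S-Dbw and its evaluation space

S-Dbw = scatter + density: scatter is the mean norm of per-cluster variance
vectors over the whole-data variance norm; density compares, for every
cluster pair, the point count within radius
`stdev = (1/k)·√(Σ_i ‖var(C_i)‖)` of the inter-centroid midpoint with the
larger count at the two centroids (floored at 1). The minimum over
k = 2..15 is selected, smallest k on ties.

The index needs a coordinate space, and the choice matters more than it
first appears. Evaluating it in the per-k spectral embedding is degenerate:
a 2-dimensional embedding hides the variance of merged clusters, so scatter
*increases* with k and k = 2 always wins, while on a unit sphere the
density radius catches no points at all. Fixed high-dimensional spaces fail
differently — isotropic noise variance makes scatter decay monotonically
and the density term never activates, pushing the argmin to the top of the
range. Both terms presuppose the low-dimensional data-space geometry the
index was designed in. The selector therefore evaluates S-Dbw in a fixed
3-dimensional classical-MDS representation of the mixed distance matrix,
one space shared by every candidate k, while labels still come from the
per-k spectral embedding. On sharply separated planted cohorts this places
a decisive minimum at the planted k (see
`tests/test_selection_stability.py`).

## Stability

For each deletion rate in {0.02, 0.04, 0.06, 0.08, 0.10} and 10
repetitions, `⌈rate·n⌉` records are removed uniformly at random, the
distance statistics are refit and the remainder re-clustered, and the
result is scored against the full-data reference (restricted to retained
records) by Hungarian-matched clustering accuracy — the best one-to-one
cluster matching's agreement fraction, via optimal assignment on the
contingency table. "Subsampling rate" is read as the fraction *removed*
(a perturbation analysis); retaining only 2 % of records while scanning k
to 15 would be ill-posed, but the complementary reading is available via
`mode="retained"`. Reference and subsample runs share the same per-k
k-means seed, so a deletion rate of 0 reproduces the reference exactly and
the reported CA isolates data perturbation. The solution is stable when
mean CA at the selected k ≥ 0.85.

All randomness descends from one master seed through named child seeds
(`child_seed(master, "step1")`, `("kmeans", k)`, `("subsample", rate_i,
rep)`, ...), so every stage is independently reproducible and two runs with
the same seed write byte-identical outputs.

## Two phases, purity, and profiling

Phase one clusters on the 30 GI symptoms only (psychological columns are
provably unused: permuting them leaves the labels unchanged). Each cluster
is profiled by z-values `(cluster mean − population mean)/population SD`
with ordinal codes used as numeric scores, plus a cluster-vs-rest
Mann–Whitney U per variable with the tie-corrected normal approximation
(no continuity correction) and effect size `r = |Z|/√N`. A variable is
**high** when z > 0.5, or when p < 0.001 and r > 0.3 *with an upward
deviation* — the significance branch requires z above the baseline because
the two-sided effect size is sign-blind and a symptom sitting far below
the population mean is low, not high. **Low** is z ≤ 0 (the radar plot's
central circle); **moderate** lies between. All thresholds live in
`LevelRuleConfig`.

A cluster is **pure** when at most `purity_max_high = 3` GI variables are
high — a codification of visual radar inspection, chosen because
single-syndrome clusters show 1–3 dominant related symptoms while overlap
clusters elevate many. Compactness is reported alongside for audit but
does not gate. Non-pure members are pooled and re-clustered with all 38
variables; the distance statistics are refit on that subpopulation, since
phase two is a new feature set on a new sample. Final reporting includes
per-cluster profiles (z, U, raw and Holm-adjusted p within cluster across
variables, r, level) and per-variable Kruskal–Wallis tests across clusters
with Conover–Iman post-hoc comparisons, Holm-corrected.

## The synthetic generator and what passing tests show

`default_archetypes` plants a miniature of the intended study design: four
pure archetypes (reflux, dyspepsia, constipation, diarrhea; 2–3 elevated
related symptoms each, low psychological burden) and three non-pure
archetypes sharing one broad 10-symptom elevation but differing in burden
(low/moderate/high). Elevated symptoms draw Likert levels from
(0.05, 0.15, 0.35, 0.45) versus a (0.55, 0.30, 0.10, 0.05) baseline;
psychological totals are rounded, clipped normals — HADS means 4/8/12
(sd 3), GHQ-12 2/5/8 (sd 3), neuroticism 16/24/32 (sd 6), remaining NEO
factors 24 (sd 6), with NEO totals on 0–48 (12 items × 0–4). Cells are
independent draws given the archetype.

Two consequences of these noise levels should be understood before reading
test results as claims about real data. First, single-draw Likert noise
makes within-cluster distances large: the between/within squared-distance
ratio for the planted GI structure is only ≈ 1.4 (a raw-code Euclidean
baseline gives ≈ 1.5), so clustering *at* the true k recovers the GI
structure well (ARI ≈ 0.88) but the S-Dbw landscape over k is shallow and
the selected k wanders between 4 and 7; selection is only decisive when
separation is far above this noise floor. Second, the psychological burden
trio is fundamentally overlapping: Bayes-optimal assignment with the true
centroids, true within-covariance, and the true informative dimensions
reaches mean ARI ≈ 0.65, so no clustering method can separate the trio
sharply at these settings. The corresponding end-to-end expectations in
`tests/test_acceptance.py` document this honestly: the metric, oracle,
stability, and triage checks pass; exact planted-k selection and sharp
trio separation do not, and cannot, at the generator's default noise.
Real cohorts also violate the generator's conditional-independence
assumption (symptoms correlate within patients beyond cluster membership),
which the inter-attribute terms of the distance are designed to exploit;
the generator therefore understates the metric's advantage over naive
baselines.

## Numerical choices and limitations

* Equal-frequency binning uses deduplicated quantile edges, so heavily tied
  columns yield fewer than B bins rather than empty ones.
* Missing cells are rejected, not imputed; validation reports every
  violating (record, variable) pair.
* Ordinal codes are 0-based in files and memory.
* k-means seeds are folded below 2³¹; eigen-decompositions use LAPACK
  subset drivers, dense matrices — intended for n up to a few thousand.
* Kruskal–Wallis on all-identical values returns (H = 0, p = 1) by contract
  rather than erroring.
* Holm adjustment within a cluster's profile treats that cluster's
  variables as the family; across-variable Kruskal–Wallis p-values are
  Holm-adjusted as their own family.
* The stability protocol compares subsample runs to the full-data
  labelling, measuring stability of the reported solution; pairwise
  co-clustering between subsample runs is a different (unimplemented)
  notion.
* Rome-criteria diagnostic labelling, raw item scoring, and plot rendering
  are out of scope; `profiles.json` carries everything a plotting layer
  needs.
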