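# Methods

This note documents the models, parameter choices, numerical decisions
and limitations behind `tfatlas`, stage by stage.

## Synthetic study conditions

All analyses run on synthetic data with planted ground truth; the
generators define the study conditions, and the defaults are fixed once:

- **Atlas** (`simulate.generate_atlas`): 9 states × 3 samples (the nine
  canonical CD8⁺ T cell states name the default design), 600 genes of
  which 120 TFs, 800 peaks on 5 chromosomes with genes on a 20 kb TSS
  grid and peaks within ±3 kb of a random gene's TSS. Expression is
  log-normal with per-gene meanlog ~ U(0, 3) and sdlog 0.5; peak
  accessibility is log-normal with meanlog ~ U(0, 2), sdlog 0.5. Each TF
  receives motif hits in 4% of peaks with log-normal affinities. Ten
  planted single-state TFs per state have their expression multiplied by
  the effect size (default 4) in their state's samples only; the same
  multiplier is applied to the accessibility of (i) peaks carrying the
  TF's motif and (ii) peaks at the TF's own locus — an active TF gene is
  itself accessible, so the planted program appears consistently in both
  omics layers. Optional wave TFs follow contiguous-run state templates
  with multiplicative log-normal noise (sd 0.3).
- **Wave profiles** (`generate_wave_scores`): additive binary templates
  (high on a contiguous run of states, run length ⌊states/waves⌋, at
  least 1) with Gaussian noise of sd 0.3 × amplitude per sample — the
  same amplitude/noise convention as the atlas wave TFs, in score space.
- **Consolidated weights** (`generate_consolidated_weights`): per
  regulatee, a TF vector from N(0, Σ) whose precision is block diagonal
  with unit diagonal and −ρ within blocks, mapped through exp(). A block
  of size *m* requires ρ < 1/(m−1) for positive definiteness; the
  generator raises otherwise. Recovery experiments use 5 (or 10) blocks
  of 10 TFs at ρ = 0.1, which implies a within-block *marginal*
  correlation of 0.5 — strong but realistic co-regulation structure.
- **KO screens** (`generate_perturb`): negative-binomial counts
  (gamma–Poisson, size parameter = dispersion, default 2) at mean depth
  5000/cell; in a cell carrying a guide against TF *t*, each regulatee
  *g*'s mean is scaled by 2^(−k·w(t→g)) with KO strength k = 1.5 — an
  activation model. Two guides per target plus two scramble guides, 200
  cells per guide, 3 hashtag replicates, 5% guide doublets (two guides
  to distinct targets), 5%/10% of genes flagged mitochondrial/ribosomal
  with library shares ~4%/~15% so the QC filters have bite without
  removing healthy cells. Truth per target is the set of regulatees in
  the TF's upper weight quartile, signed negative (activation).

What the generators do **not** emulate: read-level noise, peak calling,
doublet chemistry beyond guide co-occurrence, batch effects, cell-cycle
structure, or any real regulatory sequence. Passing recovery tests shows
the pipeline's statistics behave as designed under the stated generative
model — not that the biology of a real atlas is captured.

## GRN construction

Peaks link to every same-chromosome gene whose TSS is within
`window_bp` (default 10,000) of the peak midpoint, many-to-many,
0-based half-open coordinates, strand ignored. The window rule stands in
for measured chromatin interactions and is isolated behind
`PeakAssignment` so a loop table could be swapped in.

Each sample's node weight is the gene's expression scaled to the
sample's maximum — proportional to expression, and in (0, 1]. Edge
weights combine four factors in (0, 1] as an unweighted geometric mean
(exponents configurable): rank-normalized max motif affinity over
linking peaks, rank-normalized max accessibility over linking peaks in
the sample, and the rank-normalized expression of TF and target. Rank
normalization uses average ranks for ties (deterministic and
order-invariant) divided by n. The geometric mean keeps w ∈ (0, 1],
zero-dominant and monotone in every factor. Two distinct expression
roles coexist deliberately: the *personalization* (node weight) is
proportional to expression, so multiplicative activity shifts pass
through to the score at full strength, while the *edge factors* use
ranks so the four components share a scale.

## PageRank activity

The fixed point r = (1−d)e + d(Pᵀr + m·e), with e the normalized node
weights, P the row-normalized edge weights, and m the mass on dangling
nodes, which is returned to e (the standard personalized variant; this
choice changes scores and is therefore stated). Defaults: d = 0.85 (the
canonical damping; no value is prescribed by the activity-score method
itself), L∞ tolerance 1e−10, max 1000 iterations, error on
non-convergence. A dense linear solve of the same fixed point serves as
the test oracle; the two agree to < 1e−8 on networks up to 200 nodes.
Scores are extracted at TF rows without renormalizing over TFs. Row
z-scores use the population sd; rows that are exactly constant map to 0
(constancy is detected by exact range, because a bitwise-constant row
can still produce sd ≈ 1e−17 from round-off in the mean).

## State-selectivity catalogue

Universal TFs: grand mean = mean of per-state means (so unbalanced
designs do not overweight oversampled states), CV = sd(state means,
ddof 1)/grand mean; universal iff grand mean in the top ⌈0.10·n⌉ and
CV < 0.5. TFs with nonpositive grand mean are excluded with a warning
(CV undefined).

Specificity tests act on log scores, justified by the Shapiro–Wilk
log-normality check (`lognormality_fraction`). The default test is the
**pooled-variance unpaired t-test** (`Thresholds(welch=True)` switches
to Welch). The pooled form is the deliberate default: with 3 samples per
state the target-vs-rest comparison is 3 vs 24, where Welch's df
collapses to ≈2.5 and its critical t ≈ 3.8 — effects as large as
3-fold score shifts become undetectable at P < 0.05, defeating the
purpose of the catalogue at small replicate counts. log₂FC is the
difference of mean log₂ scores (the log ratio of geometric means). Pass
= P < 0.05 and log₂FC > 0.5, one-directional. No multiple-testing
correction by default (raw-P cutoffs are the catalogue's operating
convention); a BH-adjusted mode is available. Round 2 restricts the test
to the two focal states' samples and assigns first_state / second_state
/ shared by sign at the same cutoffs. The round-1 background includes
all non-target samples (including the similar paired state).

## Waves

PCA (column-centered, full SVD) to 10 components, with a warning if they
explain < 70% of variance; whether silhouette should be computed in PC
space or the full matrix is genuinely open — PC space (the clustering
space) is the default. k-means is undefined under correlation distances,
so the grid pairs each metric with the standard reconciliation:
Euclidean → k-means (scikit-learn), Manhattan → Lloyd-style k-medians,
Kendall/Pearson/Spearman → PAM k-medoids (Voronoi iteration) on the
1−correlation matrix; silhouette always uses the clustering's own
metric. 20 restarts per cell, best cost kept; k ranges 2–12 (bracketing
the optimum in the planted experiments); ties in the silhouette argmax
break toward smaller k, then metric order (euclidean, manhattan,
kendall, pearson, spearman). Correlation-distance matrices are computed
once per metric and reused across the k grid. Wave ids are arbitrary
labels; runs are compared by ARI.

## TF–TF association networks

Consolidation averages each TF→regulatee weight over the context's
samples, absent edges counting as 0. The variation filter drops
regulatee columns with sd (ddof 1) ≤ 1.0 across TFs — calibrated to
exp-scale consolidated weights; GRN-derived weights in (0, 1] need a
smaller cutoff, and the all-dropped error says so. Spearman ρ per TF
pair is computed over *common regulatees* (columns where both TFs have
strictly positive weight); pairs with fewer than 30 common regulatees
get ρ = 0 and a flag (unstable rank correlations are worse than no
estimate). A dense fast path (one rank transform + correlation) applies
when the weight matrix is strictly positive. The optional shrunken-ECDF
(nonparanormal) transform maps each TF row through rank/(n+1) → normal
quantile → unit variance; being a per-row monotone map it cannot change
the Spearman matrix, and it is kept only to make the estimator
convention explicit.

Pairwise-complete correlation matrices need not be PSD, so the matrix is
projected by eigenvalue clipping at 1e−8 and rescaling to unit diagonal
before the graphical lasso (scikit-learn's coordinate-descent solver; a
KKT-certificate test verifies its output independently). The λ grid has
50 log-spaced points from just above max|ρ<sub>ij</sub>| down to the
median |ρ<sub>ij</sub>| (densities ~0 to ~0.5 to first order).

**λ selection.** The operating point is a *plateau* of the
density-vs-λ curve: a maximal run of ≥ 3 consecutive grid points with
unchanged edge support (the zero-slope local minima of
|Δdensity/Δlog λ|). Among plateaus, the one with density nearest the
target (~15% of pairs) wins, ties toward larger λ; the run's midpoint is
returned. Without any plateau (e.g. strictly geometric decay) the
fallback is the grid point with density nearest the target, with a
warning. Pointwise slope minima were rejected: on noisy paths they fire
on wiggles of the dense tail and select meaninglessly small penalties.
A published penalty value can be passed directly instead of "auto".

Edges are pairs with |Θ<sub>ij</sub>| > 1e−8, weighted by the partial
correlation magnitude |−Θ<sub>ij</sub>/√(Θ<sub>ii</sub>Θ<sub>jj</sub>)|.
Density along the path is monotone in λ up to a one-edge numerical
wobble: lasso supports are not strictly nested, and coordinate descent
can flip one borderline entry at the dense (non-converged) end, so the
monotonicity check allows exactly that slack.

**Shuffle null.** Each replicate independently permutes every TF row's
regulatee weights — destroying cross-TF dependence while preserving every
row's marginal — and reruns filter → Spearman → PSD → glasso at the
*same* λ. On structured inputs (100 TFs × 1000 regulatees, 10 planted
blocks) the data-selected λ sits far above the shuffled correlation
scale (max null |ρ| ≈ 4/√n), and all null replicates return zero edges.

## Communities and enrichment

Leiden under the resolution-parametrized modularity objective
(resolution 0.9), best of 10 seeded restarts by *standard* weighted
modularity; an edgeless graph is defined to have Q = 0 with singleton
communities. Reported modularity is checked in tests against a direct
first-principles recomputation (within 1e−9). Fruchterman–Reingold
layout is seeded through Python's `random` module (which python-igraph
consumes), 200 iterations; a single node sits at the origin by
convention. Enrichment is the one-sided hypergeometric tail P(X ≥ k)
per (community, gene set) over a user universe (default: the context's
TF set; regulatee-level GMT collections are equally valid input);
significance is called on raw P < 0.05, with BH-adjusted values always
reported alongside. Gene sets disjoint from the universe are skipped
with a warning; community members outside the universe are an error.

## Perturb-seq processing

Guide calling: UMI ≥ 3 (the threshold an upstream caller would apply;
exposed because it is a substitution, not a published constant). Cells
with called guides against ≥ 2 distinct targets are flagged and
excluded. QC keeps a cell iff detected genes ≥ 200, mitochondrial
fraction ≤ 0.10, ribosomal fraction ≥ 0.05 (implemented exactly as the
filter set is stated — "less than 5% ribosomal reads … discarded" —
though the direction is unusual; the threshold is configurable), and
not multi-target; the report names the first failed rule per cell.
Normalization: ln(1 + 10⁴·count/cell total).

Cluster-distribution statistics: percentages per (replicate, target)
over clusters (rows sum to 100; empty combinations are reported missing,
never silently zero-filled), then a two-way fixed-effects additive ANOVA
(target, replicate) on one cluster's percentages, implemented in closed
form for the complete balanced design and cross-checked against an OLS
ANOVA in the tests. Fisher's LSD versus the scramble reference uses the
residual mean square and its (a−1)(b−1) df, unadjusted. Degenerate
zero-MSE tables return F = 0 (no target variance) or ∞, and LSD p = 1
for zero differences. Calibration: type-I error 0.05–0.06 at nominal
0.05 over 500 null tables.

log₂FC versus control: log₂((m̄_KO + 1)/(m̄_ctrl + 1)) on de-logged
(expm1) normalized means — the pseudocount of 1 shrinks fold changes of
weakly expressed genes toward 0, which is intentional damping. A
Wilcoxon rank-sum p-value can accompany the fold change; hurdle-model
differential expression is out of scope. Heuristic scores multiply each
regulatee's log₂FC by the GRN edge weight; high confidence requires
|log₂FC| > 0.58 (2^0.58 ≈ 1.5-fold) *and* edge weight ≥ the TF's own
0.75-quantile ("upper quantile" is not further specified; the quartile
is the default and the knob is prominent because it directly scales the
number of high-confidence calls). Mode: activated iff log₂FC < 0.
Cell clustering itself is not reimplemented — cluster labels are an
input, from any tool or from synthetic truth.

## Problem sizes

The recovery experiments use: 27-sample atlases (600 genes) for
classification (5 seeds); 140 TFs × 27 samples for wave selection
(5 seeds); 50 TFs × 4000 regulatees for glasso/Leiden recovery; 100 TFs
× 1000 regulatees with 3 null replicates for the shuffle-null check;
2400-cell screens (3 seeds) for regulatee recovery; 500 tables for ANOVA
calibration; 50 random networks ≤ 200 nodes for the PageRank oracle.
These sizes make the full suite and the acceptance script each run in a
few minutes on one CPU while leaving the planted effects comfortably
detectable.

## Known limitations

- The edge-weight formula is a principled reconstruction (geometric mean
  of four rank/scale-normalized factors), not the published internals of
  any specific activity-scoring tool; exponents are configurable.
- The TSS-window peak assignment ignores long-range regulation entirely.
- Raw-P thresholds (no FDR control) are the catalogue's convention;
  interpret counts of single-state TFs accordingly, or switch on the BH
  mode.
- The λ-selection plateau rule assumes the support path pauses on the
  true structure; on data without a clear block structure it degrades to
  nearest-target-density with a warning.
- Recovery metrics quantify behaviour under the synthetic generative
  model only.
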