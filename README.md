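# tfatlas

Transcription-factor (TF) activity analysis for multi-state cell atlases,
built around the question that motivates T cell engineering: **which TFs
drive which cell state, and which of two transcriptionally similar states
does a TF actually belong to?** The package implements the full analysis
chain — per-sample gene regulatory networks (GRNs) from paired expression
and chromatin accessibility, personalized-PageRank TF activity scores,
statistical classification of universal / single-state / multi-state TFs,
TF activity "waves" across ordered states, sparse TF–TF association
networks with community detection, and heuristic regulatee scoring for
CRISPR knockout (Perturb-seq) screens — and exercises every stage on
synthetic data with planted ground truth, so recovery is measurable.

It is written for computational biologists who want a tested, reusable
reference implementation of this kind of pipeline, with every statistical
rule explicit and configurable.

## The model in brief

**GRN.** For each sample, a weighted directed graph over genes. A peak is
linked to every gene whose TSS lies within 10 kb of the peak midpoint
(configurable; the linking rule is isolated so a measured loop table can
be substituted). The node weight of gene *g* is proportional to its
expression. An edge TF→gene carries

&nbsp;&nbsp;&nbsp;&nbsp;*w* = (*a* · *c* · *x*<sub>TF</sub> · *x*<sub>g</sub>)<sup>1/4</sup> ∈ (0, 1]

where *a* is the rank-normalized motif binding affinity, *c* the
rank-normalized accessibility at the target locus, and *x*<sub>TF</sub>,
*x*<sub>g</sub> the rank-normalized expression of the endpoints.

**TF activity.** Personalized PageRank with restart vector
*e* ∝ node weights: **r** = (1−*d*) *e* + *d* (*P*ᵀ**r** + m<sub>dangling</sub> *e*),
*d* = 0.85; a TF's activity is its steady-state score. Scores over a
network sum to 1; TF rows are extracted without renormalization.

**State selectivity.** Universal TFs: grand mean activity in the top 10%
with coefficient of variation of state means < 0.5. Remaining TFs are
tested per state on log scores (unpaired t-test, target state vs the
rest; pass at *P* < 0.05 and log₂FC > 0.5); one passing state →
single-state, several → multi-state. A second head-to-head round splits
a focal state pair (e.g. terminally exhausted vs tissue-resident memory)
into each state's single-taskers and shared multi-taskers.

**Waves.** PCA of the row-z-scored activity matrix to 10 components,
clustering over a (metric, k) grid — Euclidean k-means, Manhattan
k-medians, PAM on 1−Kendall/Pearson/Spearman — selecting the cell with
the highest average silhouette width.

**TF–TF association.** Sample networks are consolidated (mean edge
weight per TF–regulatee pair), low-variation regulatees dropped
(s.d. ≤ 1 on the consolidated scale), Spearman ρ computed per TF pair
over common regulatees, the correlation matrix projected to the nearest
PSD matrix, and a graphical lasso fit along a penalty path. λ is chosen
at the density plateau nearest ~15% connectivity; a within-row shuffle
null refit at the same λ estimates the false-discovery behaviour.
Communities come from Leiden at resolution 0.9 (best of 10 restarts by
modularity), with hypergeometric gene-set enrichment per community.

**Perturb-seq scoring.** Guide calling (UMI ≥ 3; multi-target cells
dropped), cell QC (≥ 200 detected genes, ≤ 10% mitochondrial, ≥ 5%
ribosomal reads), global-scaling log-normalization, per-replicate cluster
distributions with two-way ANOVA + Fisher's LSD versus scramble, and the
heuristic score *h* = log₂FC × *w* per TF–gene pair. A regulatee is
high-confidence if |log₂FC| > 0.58 (a 1.5-fold change) and *w* is in the
TF's upper weight quartile; the sign of log₂FC says whether the TF
activated (target drops on KO) or repressed the gene.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a synthetic
9-state atlas (27 samples, 600 genes of which 120 TFs, 800 peaks, 10
planted single-state TFs per state at effect size 4):

```bash
python analysis/01_simulate_atlas.py
python analysis/02_build_networks.py
python analysis/03_pagerank_activity.py
python analysis/04_classify_tfs.py
```

which prints (seed 1):

```
round-1 classes: {'single_state': 101, 'unclassified': 17, 'multi_state': 2}
round-2 TEXterm-vs-TRM verdicts: {'first_state': 10, 'second_state': 7, 'shared': 3}
planted single-state recovery: precision 0.861, recall 0.967
```

i.e. 101 TFs are called single-state, of which 86% are planted TFs
recovered in their true state, and the head-to-head round assigns the
TEXterm/TRM candidates to 10 TEXterm single-taskers, 7 TRM
single-taskers, and 3 shared multi-taskers. Continuing,

```bash
python analysis/05_tf_waves.py       # k=7 selected in 5/5 seeds (Pearson), ARI >= 0.94
python analysis/06_assoc_network.py  # block recovery F1 1.000; shuffle null: 0 edges
python analysis/07_communities.py    # 5 communities, modularity 0.800, all blocks enriched
python analysis/08_perturb_screen.py # regulatee recovery precision 1.000, recall 0.80-0.93
```

Each driver writes its tables under `results/`.

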