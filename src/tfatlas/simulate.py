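"""Synthetic atlases, consolidated edge-weight matrices, and Perturb-seq-style counts.

Everything downstream (GRN construction, PageRank scoring, state-selectivity
classification, wave clustering, TF-TF association networks, KO regulatee
scoring) is exercised on data produced here, with planted ground truth carried
alongside so recovery can be measured.

The generative choices emulate a multi-state CD8+ T cell atlas: log-normal
expression baselines, state-selective TF programs realised as multiplicative
activity shifts, block-structured TF-TF dependence in consolidated edge
weights, and negative-binomial KO count matrices with guide assignments,
hashtag replicates and mitochondrial/ribosomal gene fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtlasTruth",
    "AtlasBundle",
    "PerturbBundle",
    "T_CELL_STATES",
    "generate_atlas",
    "generate_wave_scores",
    "generate_consolidated_weights",
    "generate_perturb",
]

#: The nine canonical CD8+ T cell states an atlas of this shape emulates.
T_CELL_STATES = (
    "naive", "TE", "MP", "TRM", "TEM", "TCM", "TEXprog", "TEXeff", "TEXterm",
)


@dataclass
class AtlasTruth:
    """Planted ground truth of a synthetic atlas.

    Attributes
    ----------
    planted_single_state
        state label -> list of TF ids whose activity is boosted in that state.
    planted_multi_state
        TF id -> set of states (empty in the default single-state design).
    planted_wave
        TF id -> wave index in ``1..n_waves`` for TFs following a wave template.
    effect_size
        Multiplicative activity shift applied to planted TFs in their state(s).
    """

    planted_single_state: dict[str, list[str]]
    planted_multi_state: dict[str, set[str]] = field(default_factory=dict)
    planted_wave: dict[str, int] = field(default_factory=dict)
    effect_size: float = 1.0

    def single_state_of(self, tf: str) -> str | None:
        for state, tfs in self.planted_single_state.items():
            if tf in tfs:
                return state
        return None


@dataclass
class AtlasBundle:
    """A self-consistent multi-omic atlas: expression + accessibility + motifs.

    ``expression`` is genes x samples (TPM-like nonnegative reals),
    ``accessibility`` peaks x samples, ``peaks``/``genes`` carry coordinates
    (0-based half-open intervals; TSS per gene), ``motif_affinity`` is a long
    (tf, peak, affinity) table, and ``design`` maps sample id -> state label.
    """

    expression: pd.DataFrame
    accessibility: pd.DataFrame
    peaks: pd.DataFrame           # index peak id; columns chrom, start, end
    genes: pd.DataFrame           # index gene id; columns chrom, tss, strand
    motif_affinity: pd.DataFrame  # columns tf, peak, affinity
    design: pd.Series             # sample id -> state label
    truth: AtlasTruth | None = None

    @property
    def tfs(self) -> list[str]:
        return sorted(self.motif_affinity["tf"].unique())

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def states(self) -> list[str]:
        seen: list[str] = []
        for s in self.design:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of_state(self, state: str) -> list[str]:
        return list(self.design.index[self.design == state])

    def validate(self) -> None:
        if list(self.expression.columns) != list(self.design.index):
            raise ValueError("expression samples and design samples differ")
        if list(self.accessibility.columns) != list(self.design.index):
            raise ValueError("accessibility samples and design samples differ")
        missing = set(self.motif_affinity["tf"]) - set(self.expression.index)
        if missing:
            raise ValueError(f"TFs absent from expression: {sorted(missing)[:5]}")
        for name, m in (("expression", self.expression.to_numpy()),
                        ("accessibility", self.accessibility.to_numpy())):
            if (m < 0).any():
                raise ValueError(f"negative values in {name}")


@dataclass
class PerturbBundle:
    """Perturb-seq-style KO screen data with planted regulatee truth."""

    counts: pd.DataFrame          # genes x cells, nonnegative ints
    guide_umi: pd.DataFrame      # guides x cells, nonnegative ints
    guide_to_target: pd.Series   # guide id -> TF id or "scramble"
    hashtag: pd.Series           # cell -> replicate id
    gene_flags: pd.DataFrame     # index gene; columns mito, ribo (bool)
    truth: dict[str, dict[str, float]] = field(default_factory=dict)
    # truth: target TF -> {regulatee: signed effect (negative = drops on KO)}

    def validate(self) -> None:
        if set(self.counts.columns) != set(self.hashtag.index):
            raise ValueError("every cell needs a hashtag")
        if set(self.guide_umi.index) - set(self.guide_to_target.index):
            raise ValueError("guide_to_target must cover all guide ids")
        both = self.gene_flags["mito"] & self.gene_flags["ribo"]
        if both.any():
            raise ValueError("mito and ribo gene sets must be disjoint")


# ---------------------------------------------------------------------------
# atlas generation

def _wave_templates(n_waves: int, n_states: int) -> np.ndarray:
    """Binary state-profile templates: wave j is high on a contiguous run.

    Runs are spread across the state axis; run length is n_states // n_waves
    (at least 1), so templates overlap as little as the counts allow.
    """
    run = max(1, n_states // n_waves)
    starts = np.linspace(0, n_states - run, n_waves).round().astype(int)
    t = np.zeros((n_waves, n_states))
    for j, s in enumerate(starts):
        t[j, s:s + run] = 1.0
    return t


def generate_atlas(
    n_states: int = 9,
    samples_per_state: int = 3,
    n_tfs: int = 120,
    n_genes: int = 600,
    n_peaks: int = 800,
    planted_per_state: int = 10,
    effect_size: float = 4.0,
    n_waves: int = 0,
    seed: int = 0,
    state_names: list[str] | None = None,
    wave_noise_sd: float = 0.3,
) -> AtlasBundle:
    """Generate a multi-state atlas with planted single-state TF programs.

    Expression baselines are log-normal (per-gene meanlog ~ U(0, 3), sdlog
    0.5). Each planted single-state TF has its expression, and the
    accessibility of its motif-hit peaks, multiplied by ``effect_size`` in
    its state's samples only. When ``n_waves`` > 0 the remaining TFs follow
    one of ``n_waves`` contiguous-run state templates (multiplicative shift
    of ``effect_size`` on high states, log-normal noise of sd
    ``wave_noise_sd``).
    """
    if min(n_states, samples_per_state, n_tfs, n_genes, n_peaks) < 1:
        raise ValueError("all counts must be >= 1")
    if effect_size <= 1.0:
        raise ValueError(f"effect_size must exceed 1 (got {effect_size}); "
                         "no planted signal is representable otherwise")
    if n_tfs > n_genes:
        raise ValueError("n_tfs must not exceed n_genes")
    if planted_per_state * n_states > n_tfs:
        raise ValueError(
            f"planted_per_state*n_states = {planted_per_state * n_states} "
            f"exceeds n_tfs = {n_tfs}")

    rng = np.random.default_rng(seed)

    if state_names is None:
        state_names = (list(T_CELL_STATES) if n_states == 9
                       else [f"state{i+1:02d}" for i in range(n_states)])
    if len(state_names) != n_states:
        raise ValueError("state_names length must equal n_states")

    tf_ids = [f"Tf{i+1:04d}" for i in range(n_tfs)]
    gene_ids = tf_ids + [f"Gene{i+1:04d}" for i in range(n_genes - n_tfs)]
    peak_ids = [f"peak{i+1:05d}" for i in range(n_peaks)]
    samples = [f"{st}_rep{r+1}" for st in state_names
               for r in range(samples_per_state)]
    design = pd.Series([st for st in state_names
                        for _ in range(samples_per_state)],
                       index=samples, name="state")

    # gene models: a few chromosomes, TSS on a 20 kb grid
    n_chrom = 5
    chroms = np.array([f"chr{i % n_chrom + 1}" for i in range(n_genes)])
    tss = np.array([20_000 * (i // n_chrom + 1) for i in range(n_genes)])
    strand = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame({"chrom": chroms, "tss": tss, "strand": strand},
                         index=pd.Index(gene_ids, name="gene"))

    # peaks: each near a random gene's TSS (within a typical 10 kb window)
    host = rng.integers(0, n_genes, size=n_peaks)
    offset = rng.integers(-3000, 3001, size=n_peaks)
    center = np.maximum(tss[host] + offset, 300)
    peaks = pd.DataFrame({"chrom": chroms[host],
                          "start": center - 200, "end": center + 200},
                         index=pd.Index(peak_ids, name="peak"))

    # motif affinities: each TF hits a sparse random subset of peaks
    hits_per_tf = max(5, int(0.04 * n_peaks))
    rows = []
    for tf in tf_ids:
        hit = rng.choice(n_peaks, size=hits_per_tf, replace=False)
        aff = rng.lognormal(mean=0.0, sigma=1.0, size=hits_per_tf)
        rows.append(pd.DataFrame({"tf": tf,
                                  "peak": np.array(peak_ids)[hit],
                                  "affinity": aff}))
    motif = pd.concat(rows, ignore_index=True)

    # log-normal expression baseline
    meanlog = rng.uniform(0.0, 3.0, size=n_genes)
    expr = rng.lognormal(mean=meanlog[:, None], sigma=0.5,
                         size=(n_genes, len(samples)))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # accessibility baseline
    peak_meanlog = rng.uniform(0.0, 2.0, size=n_peaks)
    acc = rng.lognormal(mean=peak_meanlog[:, None], sigma=0.5,
                        size=(n_peaks, len(samples)))
    accessibility = pd.DataFrame(acc, index=peak_ids, columns=samples)

    # plant single-state TFs: boost expression and motif-linked accessibility
    planted_tfs = rng.choice(tf_ids, size=planted_per_state * n_states,
                             replace=False)
    planted: dict[str, list[str]] = {}
    for i, st in enumerate(state_names):
        chosen = list(planted_tfs[i * planted_per_state:(i + 1) * planted_per_state])
        planted[st] = chosen
        cols = design.index[design == st]
        for tf in chosen:
            expression.loc[tf, cols] *= effect_size
            # the TF's regulatory program is planted in both omics layers:
            # peaks carrying its motif (its binding footprint) and peaks at
            # its own locus (an active TF gene is itself accessible) open up
            tf_peaks = motif.loc[motif["tf"] == tf, "peak"].unique()
            accessibility.loc[tf_peaks, cols] *= effect_size
            own_tss = genes.loc[tf, "tss"]
            near_own = peaks.index[
                (peaks["chrom"] == genes.loc[tf, "chrom"])
                & (((peaks["start"] + peaks["end"]) / 2
                    - own_tss).abs() <= 10_000)]
            accessibility.loc[near_own, cols] *= effect_size

    # wave TFs among the remaining TFs
    wave_assign: dict[str, int] = {}
    if n_waves > 0:
        remaining = [t for t in tf_ids if t not in set(planted_tfs)]
        templates = _wave_templates(n_waves, n_states)
        for i, tf in enumerate(remaining):
            w = i % n_waves
            wave_assign[tf] = w + 1
            profile = templates[w]  # per-state 0/1
            for st, high in zip(state_names, profile):
                cols = design.index[design == st]
                mult = effect_size if high else 1.0
                noise = rng.lognormal(0.0, wave_noise_sd, size=len(cols))
                expression.loc[tf, cols] *= mult * noise

    truth = AtlasTruth(planted_single_state=planted,
                       planted_wave=wave_assign,
                       effect_size=effect_size)
    bundle = AtlasBundle(expression=expression, accessibility=accessibility,
                         peaks=peaks, genes=genes, motif_affinity=motif,
                         design=design, truth=truth)
    bundle.validate()
    return bundle


def generate_wave_scores(
    n_tfs: int = 140,
    n_states: int = 9,
    samples_per_state: int = 3,
    n_waves: int = 7,
    amplitude: float = 1.0,
    noise_sd_frac: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    """TF x sample activity profiles drawn from planted wave templates.

    Each TF follows one of ``n_waves`` contiguous-run state templates
    (additive, amplitude ``amplitude``) plus Gaussian noise of sd
    ``noise_sd_frac * amplitude`` per sample. Returns (scores, design,
    planted wave map).
    """
    if n_waves < 1 or n_waves > n_states:
        raise ValueError("need 1 <= n_waves <= n_states")
    rng = np.random.default_rng(seed)
    states = [f"state{i+1:02d}" for i in range(n_states)]
    samples = [f"{st}_rep{r+1}" for st in states for r in range(samples_per_state)]
    design = pd.Series([st for st in states for _ in range(samples_per_state)],
                       index=samples, name="state")
    templates = _wave_templates(n_waves, n_states) * amplitude
    tf_ids = [f"Tf{i+1:04d}" for i in range(n_tfs)]
    assign = {tf: (i % n_waves) + 1 for i, tf in enumerate(tf_ids)}
    per_sample = np.repeat(
        np.stack([templates[assign[tf] - 1] for tf in tf_ids]),
        samples_per_state, axis=1)
    noise = rng.normal(0.0, noise_sd_frac * amplitude, size=per_sample.shape)
    scores = pd.DataFrame(per_sample + noise, index=tf_ids, columns=samples)
    return scores, design, assign


# ---------------------------------------------------------------------------
# consolidated edge-weight matrices with block-structured TF-TF dependence

def _block_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def block_precision(n_tfs: int, n_blocks: int, partial_corr: float) -> tuple[np.ndarray, np.ndarray]:
    """Block-diagonal precision matrix with the stated within-block partial
    correlation (unit diagonal, off-diagonal -partial_corr inside blocks).

    Returns (precision, block labels). Raises if the requested matrix is not
    positive definite (needs partial_corr < 1/(block size - 1)).
    """
    if not (n_blocks >= 1 and n_blocks <= n_tfs):
        raise ValueError("need 1 <= n_blocks <= n_tfs")
    if not (0.0 < partial_corr < 1.0):
        raise ValueError("within_block_partial_corr must be in (0, 1)")
    sizes = _block_sizes(n_tfs, n_blocks)
    theta = np.eye(n_tfs)
    labels = np.zeros(n_tfs, dtype=int)
    pos = 0
    for b, m in enumerate(sizes):
        sl = slice(pos, pos + m)
        theta[sl, sl] = -partial_corr
        np.fill_diagonal(theta[sl, sl], 1.0)
        labels[sl] = b
        pos += m
    if np.linalg.eigvalsh(theta).min() <= 1e-10:
        raise ValueError(
            f"requested precision is not positive definite: partial_corr="
            f"{partial_corr} too large for block size {max(sizes)} "
            f"(needs < 1/(block_size-1))")
    return theta, labels


def generate_consolidated_weights(
    n_tfs: int,
    n_regulatees: int,
    n_blocks: int,
    within_block_partial_corr: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Consolidated TF x regulatee weight matrix with planted TF-TF blocks.

    Per regulatee, a TF-vector is drawn from N(0, Sigma) with block-diagonal
    precision Sigma^-1 (unit diagonal, within-block off-diagonal entries
    -within_block_partial_corr), then mapped through exp() to positive
    weights. Returns (weights DataFrame, planted block labels).
    """
    theta, labels = block_precision(n_tfs, n_blocks, within_block_partial_corr)
    sigma = np.linalg.inv(theta)
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(n_tfs), sigma, size=n_regulatees,
                                method="cholesky")  # regulatees x TFs
    weights = pd.DataFrame(
        np.exp(z.T),
        index=[f"Tf{i+1:04d}" for i in range(n_tfs)],
        columns=[f"Gene{j+1:05d}" for j in range(n_regulatees)],
    )
    return weights, labels


# ---------------------------------------------------------------------------
# Perturb-seq-style KO counts

def generate_perturb(
    atlas: AtlasBundle,
    network,
    targets: list[str],
    cells_per_guide: int = 200,
    n_replicates: int = 3,
    ko_strength: float = 1.5,
    nb_dispersion: float = 2.0,
    mito_frac: float = 0.05,
    ribo_frac: float = 0.10,
    doublet_fraction: float = 0.05,
    guides_per_target: int = 2,
    n_scramble_guides: int = 2,
    mean_depth: float = 5000.0,
    seed: int = 0,
) -> PerturbBundle:
    """Simulate a pooled KO screen read out by single-cell RNA-seq.

    Cells carry guides against ``targets`` (plus scramble controls); in a
    cell whose guide hits TF t, the mean expression of each regulatee g is
    scaled by 2**(-ko_strength * w(t->g)) — an activation model where losing
    the TF lowers its targets. Counts are negative binomial with size
    parameter ``nb_dispersion`` (variance mu + mu^2/size). A
    ``doublet_fraction`` of cells carry a second guide against a distinct
    target. Truth lists, per target, the regulatees whose edge weight lies
    in that TF's upper quartile, with signed effect.
    """
    if len(targets) == 0:
        raise ValueError("targets must be nonempty")
    if ko_strength < 0:
        raise ValueError("ko_strength must be >= 0")
    edges = network.edges
    known_tfs = set(edges["tf"])
    missing = set(targets) - known_tfs
    if missing:
        raise ValueError(f"targets absent from network: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    genes = list(atlas.expression.index)
    n_genes = len(genes)

    # baseline per-gene mean counts proportional to atlas mean expression
    base = atlas.expression.mean(axis=1).to_numpy().astype(float)
    base = base / base.sum() * mean_depth

    # disjoint mito / ribo flags
    n_mito = int(round(mito_frac * n_genes))
    n_ribo = int(round(ribo_frac * n_genes))
    flagged = rng.choice(n_genes, size=n_mito + n_ribo, replace=False)
    mito_idx, ribo_idx = flagged[:n_mito], flagged[n_mito:]
    gene_flags = pd.DataFrame(False, index=genes, columns=["mito", "ribo"])
    gene_flags.iloc[mito_idx, 0] = True
    gene_flags.iloc[ribo_idx, 1] = True
    # give flagged genes a realistic share of the library (~4% mito, ~15% ribo)
    other = np.setdiff1d(np.arange(n_genes), flagged)
    for idx, share in ((mito_idx, 0.04), (ribo_idx, 0.15)):
        if len(idx) and base[idx].sum() > 0:
            base[idx] *= share * base[other].sum() / ((1 - 0.04 - 0.15) * base[idx].sum())
    base = base / base.sum() * mean_depth

    # KO fold-change profile per target TF
    ko_mult = {}
    for t in targets:
        sub = edges[edges["tf"] == t]
        mult = np.ones(n_genes)
        gidx = pd.Index(genes).get_indexer(sub["gene"])
        mult[gidx] = 2.0 ** (-ko_strength * sub["w"].to_numpy())
        ko_mult[t] = mult
    ko_mult["scramble"] = np.ones(n_genes)

    # guide library
    guide_rows = []
    for t in targets:
        for g in range(guides_per_target):
            guide_rows.append((f"g{t}_{g+1}", t))
    for g in range(n_scramble_guides):
        guide_rows.append((f"gScramble_{g+1}", "scramble"))
    guide_ids = [g for g, _ in guide_rows]
    guide_to_target = pd.Series({g: t for g, t in guide_rows}, name="target")

    n_cells = cells_per_guide * len(guide_ids)
    cell_ids = [f"cell{i+1:06d}" for i in range(n_cells)]
    primary_guide = np.repeat(np.arange(len(guide_ids)), cells_per_guide)
    primary_guide = rng.permutation(primary_guide)

    # doublets: second guide against a *distinct* target
    is_doublet = rng.random(n_cells) < doublet_fraction
    second_guide = np.full(n_cells, -1)
    for i in np.flatnonzero(is_doublet):
        t0 = guide_to_target.iloc[primary_guide[i]]
        choices = [j for j, (_, t) in enumerate(guide_rows) if t != t0]
        second_guide[i] = rng.choice(choices)

    hashtag = pd.Series(
        [f"rep{(i % n_replicates) + 1}" for i in range(n_cells)],
        index=cell_ids, name="replicate")

    # counts: negative binomial via gamma-Poisson mixture
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    size = float(nb_dispersion)
    for i in range(n_cells):
        mu = base * ko_mult[guide_to_target.iloc[primary_guide[i]]]
        if second_guide[i] >= 0:
            mu = mu * ko_mult[guide_to_target.iloc[second_guide[i]]]
        lam = rng.gamma(shape=size, scale=mu / size)
        counts[:, i] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)

    # guide UMI table: called guides get high UMI, ambient noise stays low
    umi = rng.poisson(0.05, size=(len(guide_ids), n_cells))
    umi[primary_guide, np.arange(n_cells)] = 5 + rng.poisson(15, size=n_cells)
    dbl = np.flatnonzero(second_guide >= 0)
    umi[second_guide[dbl], dbl] = 5 + rng.poisson(15, size=len(dbl))
    guide_umi = pd.DataFrame(umi, index=guide_ids, columns=cell_ids)

    # planted truth: upper-quartile regulatees per target, activation sign
    truth: dict[str, dict[str, float]] = {}
    for t in targets:
        sub = edges[edges["tf"] == t]
        q = sub["w"].quantile(0.75)
        regs = sub.loc[sub["w"] >= q]
        truth[t] = {g: -float(w) for g, w in zip(regs["gene"], regs["w"])}

    bundle = PerturbBundle(counts=counts_df, guide_umi=guide_umi,
                           guide_to_target=guide_to_target, hashtag=hashtag,
                           gene_flags=gene_flags, truth=truth)
    bundle.validate()
    return bundle
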