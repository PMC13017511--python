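"""Perturb-seq-style processing and heuristic regulatee scoring.

Stages: guide calling from UMI counts (cells with guides against two or
more distinct targets are flagged and excluded), per-cell QC (detected
genes / mitochondrial fraction / ribosomal fraction), global-scaling
log-normalization, per-replicate cluster-distribution statistics against
the scramble control (two-way ANOVA with Fisher's LSD), control-referenced
log2 fold changes, and heuristic regulatee scores h = log2FC x edge weight
with the high-confidence rule (|log2FC| > 0.58, i.e. a 1.5-fold change,
and edge weight in the TF's own upper weight quantile). The sign of the
log2FC reports the regulatory mode: a target that drops when its TF is
knocked out was activated by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PerturbBundle

__all__ = [
    "GuideAssignment",
    "QCReport",
    "assign_guides",
    "qc_filter",
    "lognormalize",
    "cluster_fractions",
    "anova_lsd",
    "log2fc_vs_control",
    "log2fc_table",
    "heuristic_scores",
]


@dataclass
class GuideAssignment:
    """Per-cell called guides and targets."""

    table: pd.DataFrame  # index cell; columns: targets (tuple), n_called, multi_target
    umi_threshold: int

    def cells_of_target(self, target: str) -> list[str]:
        t = self.table
        mask = (~t["multi_target"]) & (t["targets"].map(
            lambda s: len(s) == 1 and s[0] == target))
        return list(t.index[mask])


@dataclass
class QCReport:
    table: pd.DataFrame  # per cell: n_genes_detected, mito_fraction,
    #                      ribo_fraction, kept, reason
    thresholds: dict

    @property
    def kept_cells(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def assign_guides(pb: PerturbBundle, umi_threshold: int = 3,
                  ) -> GuideAssignment:
    """Call a guide in a cell iff its UMI count is >= the threshold; a
    cell's target set is the distinct non-scramble targets of its called
    guides (scramble-only cells get the target "scramble")."""
    called = pb.guide_umi >= umi_threshold
    targets_of_guide = pb.guide_to_target
    rows = {}
    for cell in pb.guide_umi.columns:
        guides = list(pb.guide_umi.index[called[cell]])
        tset = sorted({targets_of_guide[g] for g in guides}
                      - {"scramble"})
        if not tset and any(targets_of_guide[g] == "scramble" for g in guides):
            tset = ["scramble"]
        rows[cell] = (tuple(tset), len(guides),
                      len([t for t in tset if t != "scramble"]) >= 2)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["targets", "n_called",
                                            "multi_target"])
    return GuideAssignment(table=table, umi_threshold=umi_threshold)


def qc_filter(pb: PerturbBundle, ga: GuideAssignment,
              min_genes: int = 200, max_mito: float = 0.10,
              min_ribo: float = 0.05) -> QCReport:
    """Keep a cell iff it has >= ``min_genes`` detected genes, mitochondrial
    read fraction <= ``max_mito``, ribosomal read fraction >= ``min_ribo``,
    and is not multi-target. The reason column names the first failed rule.
    """
    counts = pb.counts
    total = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    mito = counts.loc[pb.gene_flags.index[pb.gene_flags["mito"]]].sum(axis=0)
    ribo = counts.loc[pb.gene_flags.index[pb.gene_flags["ribo"]]].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = (mito / total).fillna(0.0)
        ribo_frac = (ribo / total).fillna(0.0)
    multi = ga.table["multi_target"].reindex(counts.columns, fill_value=False)

    kept = []
    reason = []
    for cell in counts.columns:
        if n_genes[cell] < min_genes:
            kept.append(False); reason.append("min_genes")
        elif mito_frac[cell] > max_mito:
            kept.append(False); reason.append("max_mito")
        elif ribo_frac[cell] < min_ribo:
            kept.append(False); reason.append("min_ribo")
        elif multi[cell]:
            kept.append(False); reason.append("multi_target")
        else:
            kept.append(True); reason.append("")
    table = pd.DataFrame({"n_genes_detected": n_genes,
                          "mito_fraction": mito_frac,
                          "ribo_fraction": ribo_frac,
                          "kept": kept, "reason": reason},
                         index=counts.columns)
    return QCReport(table=table, thresholds={"min_genes": min_genes,
                                             "max_mito": max_mito,
                                             "min_ribo": min_ribo})


def lognormalize(counts: pd.DataFrame, scale: float = 10_000.0,
                 ) -> pd.DataFrame:
    """Global-scaling normalization: x -> ln(1 + scale * count / cell_total)."""
    total = counts.sum(axis=0)
    if (total <= 0).any():
        bad = list(total.index[total <= 0][:5])
        raise ValueError(f"zero-total cell(s) {bad}; these should have "
                         f"failed QC")
    return np.log1p(scale * counts / total)


def cluster_fractions(cells: list[str], cluster_labels: pd.Series,
                      ga: GuideAssignment, hashtag: pd.Series,
                      ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Percentage distribution over clusters per (replicate, target).

    Rows are indexed by (replicate, target) and sum to 100 over the
    cluster columns. Combinations with no cells are returned in the
    missing list rather than silently zero-filled.
    """
    t = ga.table.loc[cells]
    single = t[~t["multi_target"] & (t["targets"].map(len) == 1)]
    df = pd.DataFrame({
        "cell": single.index,
        "target": single["targets"].map(lambda s: s[0]),
        "replicate": hashtag.reindex(single.index),
        "cluster": cluster_labels.reindex(single.index),
    })
    if df["cluster"].isna().any() or df["replicate"].isna().any():
        raise ValueError("every kept cell needs a cluster label and replicate")
    counts = (df.groupby(["replicate", "target", "cluster"], observed=True)
              .size().unstack("cluster", fill_value=0))
    fractions = counts.div(counts.sum(axis=1), axis=0) * 100.0
    all_targets = sorted(df["target"].unique())
    all_reps = sorted(df["replicate"].unique())
    missing = [(r, tg) for r in all_reps for tg in all_targets
               if (r, tg) not in fractions.index]
    return fractions, missing


def anova_lsd(fractions: pd.DataFrame, cluster: str,
              reference_target: str = "scramble",
              ) -> tuple[pd.DataFrame, dict]:
    """Two-way fixed-effects ANOVA (target x replicate, additive) on one
    cluster's percentages, then Fisher's LSD versus the reference target.

    Fisher's LSD is the unadjusted pairwise t-statistic using the ANOVA
    residual mean square and residual degrees of freedom. The design must
    be complete (every target observed in every replicate) with >= 2
    replicates.
    """
    y = fractions[cluster].unstack("target")  # replicates x targets
    if y.isna().any().any():
        raise ValueError("incomplete design: every target needs a value in "
                         "every replicate")
    b, a = y.shape  # b replicates, a targets
    if b < 2:
        raise ValueError("need >= 2 replicates (no residual df otherwise)")
    if reference_target not in y.columns:
        raise ValueError(f"reference target {reference_target!r} absent")
    Y = y.to_numpy(dtype=float)
    grand = Y.mean()
    target_means = Y.mean(axis=0)
    rep_means = Y.mean(axis=1)
    ss_target = b * ((target_means - grand) ** 2).sum()
    ss_rep = a * ((rep_means - grand) ** 2).sum()
    resid = Y - target_means[None, :] - rep_means[:, None] + grand
    ss_res = (resid ** 2).sum()
    df_target, df_rep, df_res = a - 1, b - 1, (a - 1) * (b - 1)
    mse = ss_res / df_res
    if mse > 0:
        f_target = (ss_target / df_target) / mse
    else:
        f_target = np.inf if ss_target > 0 else 0.0
    p_target = float(stats.f.sf(f_target, df_target, df_res))

    ref_mean = y[reference_target].mean()
    rows = []
    for tg in y.columns:
        if tg == reference_target:
            continue
        diff = y[tg].mean() - ref_mean
        if mse > 0:
            tstat = diff / np.sqrt(2.0 * mse / b)
            p = float(2.0 * stats.t.sf(abs(tstat), df_res))
        else:
            tstat = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append((tg, diff, tstat, p))
    lsd = pd.DataFrame(rows, columns=["target", "mean_diff", "t", "p_value"])
    anova = {"ss_target": ss_target, "ss_replicate": ss_rep,
             "ss_residual": ss_res, "df_target": df_target,
             "df_replicate": df_rep, "df_residual": df_res,
             "ms_residual": mse, "F_target": float(f_target),
             "p_target": p_target}
    return lsd, anova


def log2fc_vs_control(norm: pd.DataFrame, ko_cells: list[str],
                      control_cells: list[str], gene: str,
                      pseudo: float = 1.0) -> float:
    """log2 of the pseudocounted ratio of de-logged normalized means,
    KO versus control (de-logged = expm1 of the normalized values)."""
    if len(ko_cells) == 0 or len(control_cells) == 0:
        raise ValueError("both groups must be nonempty")
    ko = float(np.expm1(norm.loc[gene, ko_cells]).mean())
    ctrl = float(np.expm1(norm.loc[gene, control_cells]).mean())
    return float(np.log2((ko + pseudo) / (ctrl + pseudo)))


def log2fc_table(norm: pd.DataFrame, ga: GuideAssignment,
                 kept_cells: list[str], targets: list[str],
                 reference_target: str = "scramble",
                 pseudo: float = 1.0) -> pd.DataFrame:
    """Genes x targets matrix of control-referenced log2 fold changes."""
    kept = set(kept_cells)
    ctrl = [c for c in ga.cells_of_target(reference_target) if c in kept]
    if not ctrl:
        raise ValueError("no control cells after filtering")
    ctrl_mean = np.expm1(norm[ctrl]).mean(axis=1)
    cols = {}
    for t in targets:
        cells = [c for c in ga.cells_of_target(t) if c in kept]
        if not cells:
            raise ValueError(f"no cells for target {t!r} after filtering")
        ko_mean = np.expm1(norm[cells]).mean(axis=1)
        cols[t] = np.log2((ko_mean + pseudo) / (ctrl_mean + pseudo))
    return pd.DataFrame(cols)


def heuristic_scores(network, lfc: pd.DataFrame,
                     lfc_min: float = 0.58,
                     weight_quantile: float = 0.75) -> pd.DataFrame:
    """Heuristic regulatee scores h = log2FC x edge weight per (TF, gene).

    A pair is high-confidence iff |log2FC| > ``lfc_min`` (0.58 ~ a
    1.5-fold change) and the edge weight is in the TF's own upper weight
    quantile (>= the ``weight_quantile`` quantile of all edge weights
    attributed to that TF). Mode is "activated" when the target drops on
    KO (log2FC < 0) and "repressed" otherwise.

    ``network`` may be a per-sample RegulatoryNetwork (``edges`` frame) or
    a ConsolidatedNetwork (``weights`` matrix); ``lfc`` is the genes x
    targets log2FC table.
    """
    if hasattr(network, "edges"):
        e = network.edges
        pairs = e[["tf", "gene", "w"]]
    else:
        w = network.weights.stack()
        w = w[w > 0]
        pairs = w.rename("w").reset_index().rename(
            columns={"tf": "tf", "level_0": "tf", "level_1": "gene",
                     "gene": "gene"})
        pairs.columns = ["tf", "gene", "w"]
    missing = set(lfc.columns) - set(pairs["tf"])
    if missing:
        raise ValueError(f"TF(s) absent from network: {sorted(missing)}")
    rows = []
    for tf in lfc.columns:
        sub = pairs[pairs["tf"] == tf]
        qthr = sub["w"].quantile(weight_quantile)
        for _, r in sub.iterrows():
            gene = r["gene"]
            if gene not in lfc.index:
                continue
            l2 = float(lfc.loc[gene, tf])
            w = float(r["w"])
            high = bool(abs(l2) > lfc_min and w >= qthr)
            mode = "activated" if l2 < 0 else "repressed"
            rows.append((tf, gene, l2, w, l2 * w, high, mode))
    return pd.DataFrame(rows, columns=["tf", "gene", "log2fc", "w", "score",
                                       "high_confidence", "mode"])
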