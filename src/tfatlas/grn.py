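"""Per-sample weighted, directed TF->gene regulatory networks.

A network is built for one sample from three ingredients: gene expression
(node weights), chromatin accessibility at peaks linked to each target gene,
and TF->peak motif binding affinity. Peaks are linked to genes by a TSS
window rule (a peak regulates every gene whose TSS lies within ``window_bp``
of the peak midpoint), kept behind :class:`PeakAssignment` so a measured
chromatin-loop table could be substituted.

Each edge weight combines four rank-normalized factors — binding affinity
``a``, accessibility ``c``, and the expression of TF and target — as an
(optionally weighted) geometric mean, keeping w in (0, 1] and monotone in
every factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import AtlasBundle

__all__ = [
    "PeakAssignment",
    "RegulatoryNetwork",
    "assign_peaks_to_genes",
    "rank_normalize",
    "build_grn",
    "build_all_grns",
]


@dataclass
class PeakAssignment:
    """Peak -> gene links (many-to-many) under a TSS-distance window."""

    pairs: pd.DataFrame  # columns: peak, gene
    window_bp: int


@dataclass
class RegulatoryNetwork:
    """One sample's weighted directed GRN.

    ``node_weight`` holds each gene's expression in the sample scaled to
    unit maximum (proportional to expression level); ``edges`` has one row
    per TF->gene interaction with the combined weight ``w`` and its four
    factors (a, c, x_tf, x_g).
    """

    sample: str | None
    node_weight: pd.Series
    edges: pd.DataFrame  # columns: tf, gene, w, a, c, x_tf, x_g

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def validate(self) -> None:
        nodes = set(self.node_weight.index)
        if not set(self.edges["tf"]).issubset(nodes):
            raise ValueError("edge TF endpoint missing from nodes")
        if not set(self.edges["gene"]).issubset(nodes):
            raise ValueError("edge gene endpoint missing from nodes")
        w = self.edges["w"].to_numpy()
        if len(w) and not ((w > 0) & (w <= 1)).all():
            raise ValueError("edge weights must lie in (0, 1]")


def rank_normalize(values) -> np.ndarray:
    """Map nonnegative values to (0, 1] by average-rank / n.

    Ties receive average ranks, so the result is deterministic and invariant
    to input order; the maximum always maps to 1 on tie-free vectors.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("rank_normalize expects a nonempty 1-D vector")
    if (arr < 0).any():
        raise ValueError("rank_normalize requires nonnegative input")
    return rankdata(arr, method="average") / arr.size


def assign_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                          window_bp: int = 10_000) -> PeakAssignment:
    """Link each peak to every same-chromosome gene whose TSS is within
    ``window_bp`` of the peak midpoint (0-based half-open intervals,
    strand ignored for distance)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    bad = peaks.index[(peaks["end"] <= peaks["start"])]
    if len(bad):
        raise ValueError(f"malformed interval (end <= start) for peak(s): "
                         f"{list(bad[:5])}")
    out_peaks: list[str] = []
    out_genes: list[str] = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        mid = (psub["start"].to_numpy() + psub["end"].to_numpy()) / 2.0
        tss = gsub["tss"].to_numpy(dtype=float)
        order = np.argsort(tss)
        tss_sorted = tss[order]
        lo = np.searchsorted(tss_sorted, mid - window_bp, side="left")
        hi = np.searchsorted(tss_sorted, mid + window_bp, side="right")
        for pi, (l, h) in enumerate(zip(lo, hi)):
            if h > l:
                out_peaks.extend([psub.index[pi]] * (h - l))
                out_genes.extend(gsub.index[order[l:h]])
    pairs = pd.DataFrame({"peak": out_peaks, "gene": out_genes})
    return PeakAssignment(pairs=pairs, window_bp=window_bp)


def build_grn(atlas: AtlasBundle, sample_id: str,
              assignment: PeakAssignment, min_affinity: float = 0.0,
              exponents: tuple[float, float, float, float] = (1, 1, 1, 1),
              ) -> RegulatoryNetwork:
    """Build the sample's GRN.

    Node weights are proportional to each gene's expression in this sample
    (scaled to unit maximum); they drive the PageRank personalization. For
    each (TF, gene) pair connected by at least one assigned peak whose
    motif affinity passes ``min_affinity``: ``a`` is the rank-normalized
    max affinity over linking peaks, ``c`` the rank-normalized max
    accessibility over linking peaks in this sample, and x_tf / x_g the
    rank-normalized expression of the endpoints — four comparable factors
    in (0, 1]. The combined weight is their geometric mean (exponents
    configurable, normalized to sum 1).
    """
    if sample_id not in atlas.expression.columns:
        raise ValueError(f"sample {sample_id!r} not present in atlas")
    expr = atlas.expression[sample_id]
    if expr.max() <= 0:
        raise ValueError(f"sample {sample_id!r} has no expressed gene")
    # node weight proportional to expression, scaled to unit maximum so
    # that the expression factors (and hence w) stay in (0, 1]
    node_weight = pd.Series(expr.to_numpy(dtype=float) / float(expr.max()),
                            index=expr.index, name="node_weight")

    motifs = atlas.motif_affinity
    missing = set(motifs["tf"]) - set(expr.index)
    if missing:
        raise ValueError(f"TF(s) absent from expression matrix: "
                         f"{sorted(missing)[:5]}")
    motifs = motifs[motifs["affinity"] >= min_affinity]

    cand = motifs.merge(assignment.pairs, on="peak")
    if cand.empty:
        return RegulatoryNetwork(sample=sample_id, node_weight=node_weight,
                                 edges=pd.DataFrame(columns=["tf", "gene", "w",
                                                             "a", "c", "x_tf",
                                                             "x_g"]))
    acc = atlas.accessibility[sample_id]
    cand = cand.assign(acc=acc.reindex(cand["peak"]).to_numpy())
    grouped = (cand.groupby(["tf", "gene"], sort=True)
               .agg(a_raw=("affinity", "max"), c_raw=("acc", "max"))
               .reset_index())

    e = np.asarray(exponents, dtype=float)
    if (e < 0).any() or e.sum() <= 0:
        raise ValueError("exponents must be nonnegative with positive sum")
    e = e / e.sum()
    a = rank_normalize(grouped["a_raw"].to_numpy())
    c = rank_normalize(grouped["c_raw"].to_numpy())
    xrank = pd.Series(rank_normalize(expr.to_numpy()), index=expr.index)
    x_tf = xrank.reindex(grouped["tf"]).to_numpy()
    x_g = xrank.reindex(grouped["gene"]).to_numpy()
    w = a ** e[0] * c ** e[1] * x_tf ** e[2] * x_g ** e[3]
    edges = pd.DataFrame({"tf": grouped["tf"], "gene": grouped["gene"],
                          "w": w, "a": a, "c": c, "x_tf": x_tf, "x_g": x_g})
    net = RegulatoryNetwork(sample=sample_id, node_weight=node_weight,
                            edges=edges)
    net.validate()
    return net


def build_all_grns(atlas: AtlasBundle, window_bp: int = 10_000,
                   min_affinity: float = 0.0) -> dict[str, RegulatoryNetwork]:
    """One GRN per atlas sample, sharing a single peak->gene assignment."""
    assignment = assign_peaks_to_genes(atlas.peaks, atlas.genes, window_bp)
    return {s: build_grn(atlas, s, assignment, min_affinity)
            for s in atlas.samples}
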