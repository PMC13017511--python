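"""Readers and writers for the pipeline's on-disk formats.

Matrices go out as TSV (and MTX with row/column label files for the large
sparse ones), peaks as BED (0-based half-open), gene models and design
tables as TSV, motif affinities as a 3-column TSV, network edge lists as
(optionally gzipped) TSV, gene sets as GMT, and planted truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .grn import RegulatoryNetwork
from .simulate import AtlasBundle, AtlasTruth, PerturbBundle

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv",
    "write_matrix_mtx", "read_matrix_mtx",
    "write_bed", "read_bed",
    "write_atlas", "read_atlas",
    "write_network", "read_network",
    "write_perturb", "read_gmt", "write_gmt",
]


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_mtx(df: pd.DataFrame, prefix) -> None:
    """MTX + <prefix>.rows / <prefix>.cols label files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")),
                     sp.csr_matrix(df.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(map(str, df.index)) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(map(str, df.columns)) + "\n")


def read_matrix_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    m = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    return pd.DataFrame(m, index=rows, columns=cols)


def write_bed(peaks: pd.DataFrame, path) -> None:
    """BED: chrom, start, end, name (0-based half-open)."""
    out = peaks.reset_index()
    out = out[["chrom", "start", "end", out.columns[0]]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "peak"])
    return df.set_index("peak")[["chrom", "start", "end"]]


def write_atlas(bundle: AtlasBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(bundle.expression, out / "expression.tsv")
    write_matrix_tsv(bundle.accessibility, out / "accessibility.tsv")
    write_bed(bundle.peaks, out / "peaks.bed")
    bundle.genes.to_csv(out / "genes.tsv", sep="\t")
    bundle.motif_affinity.to_csv(out / "motifs.tsv", sep="\t", index=False)
    bundle.design.rename("state").to_csv(out / "design.tsv", sep="\t")
    if bundle.truth is not None:
        t = bundle.truth
        (out / "truth.json").write_text(json.dumps({
            "planted_single_state": t.planted_single_state,
            "planted_multi_state": {k: sorted(v)
                                    for k, v in t.planted_multi_state.items()},
            "planted_wave": t.planted_wave,
            "effect_size": t.effect_size,
        }, indent=1))


def read_atlas(indir) -> AtlasBundle:
    d = Path(indir)
    truth = None
    tp = d / "truth.json"
    if tp.exists():
        raw = json.loads(tp.read_text())
        truth = AtlasTruth(
            planted_single_state=raw["planted_single_state"],
            planted_multi_state={k: set(v)
                                 for k, v in raw["planted_multi_state"].items()},
            planted_wave=raw["planted_wave"],
            effect_size=raw["effect_size"])
    design = pd.read_csv(d / "design.tsv", sep="\t", index_col=0)["state"]
    bundle = AtlasBundle(
        expression=read_matrix_tsv(d / "expression.tsv"),
        accessibility=read_matrix_tsv(d / "accessibility.tsv"),
        peaks=read_bed(d / "peaks.bed"),
        genes=pd.read_csv(d / "genes.tsv", sep="\t", index_col=0),
        motif_affinity=pd.read_csv(d / "motifs.tsv", sep="\t"),
        design=design, truth=truth)
    bundle.validate()
    return bundle


def write_network(net: RegulatoryNetwork, prefix, gzip: bool = True) -> None:
    """Edge-list TSV (tf, gene, w, a, c, x_tf, x_g) + node-weight TSV."""
    prefix = Path(prefix)
    suffix = ".edges.tsv.gz" if gzip else ".edges.tsv"
    net.edges.to_csv(str(prefix) + suffix, sep="\t", index=False)
    net.node_weight.rename("node_weight").to_csv(
        str(prefix) + ".nodes.tsv", sep="\t")


def read_network(prefix, sample: str | None = None,
                 gzip: bool = True) -> RegulatoryNetwork:
    prefix = Path(prefix)
    suffix = ".edges.tsv.gz" if gzip else ".edges.tsv"
    edges = pd.read_csv(str(prefix) + suffix, sep="\t")
    nodes = pd.read_csv(str(prefix) + ".nodes.tsv", sep="\t",
                        index_col=0)["node_weight"]
    return RegulatoryNetwork(sample=sample, node_weight=nodes, edges=edges)


def write_perturb(pb: PerturbBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_mtx(pb.counts, out / "counts")
    pb.guide_umi.to_csv(out / "guide_umi.tsv", sep="\t")
    pb.guide_to_target.rename("target").to_csv(out / "guides.tsv", sep="\t")
    pb.hashtag.rename("replicate").to_csv(out / "hashtags.tsv", sep="\t")
    pb.gene_flags.to_csv(out / "gene_flags.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(pb.truth, indent=1))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")
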