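"""Infer TF-TF association networks by Spearman + graphical lasso.

Two experiments. (1) Planted truth: block-structured consolidated weights
(50 TFs, 5 blocks) -> auto-selected lambda -> edge-support recovery; then
the shuffle-null false-discovery check at the same lambda on a larger
structured matrix (100 TFs x 1000 regulatees). (2) Atlas contexts: the
per-sample GRNs are consolidated for the TEXterm and TRM states and fit
with the same pipeline (GRN weights live in (0,1], so the variation
filter uses an sd cutoff matched to that scale). Writes edge lists and
the sparsity curve under results/assoc/.
"""

from pathlib import Path

import pandas as pd

from tfatlas import assoc, experiments, grn, io

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    adir = OUT / "assoc"
    adir.mkdir(parents=True, exist_ok=True)

    gl = experiments.glasso_recovery(seed=1)
    print(f"planted 5-block recovery: support F1 {gl['f1']:.3f} at "
          f"lambda {gl['lambda']:.3f} (density {gl['density']:.3f}); "
          f"path density monotone: {gl['density_monotone']}")

    null = experiments.association_null_fdr(seed=1)
    print(f"shuffle null at lambda {null['lambda']:.3f}: real graph has "
          f"{null['real_edges']} edges, null replicates "
          f"{null['null_counts']} -> mean {null['null_mean']:.1f}")

    atlas = io.read_atlas(OUT / "atlas")
    networks = grn.build_all_grns(atlas)
    for context in ("TEXterm", "TRM"):
        samples = atlas.samples_of_state(context)
        cn = assoc.consolidate(networks, samples, atlas.tfs,
                               context=context)
        graph = assoc.fit_association_graph(cn, sd_min=0.05, min_common=5)
        graph.edges.to_csv(adir / f"{context}_edges.tsv", sep="\t",
                           index=False)
        print(f"{context}: {len(graph.nodes)} TFs, {len(graph.edges)} "
              f"edges (density {graph.density:.3f}) at "
              f"lambda {graph.lambda_:.3f}")

    # sparsity curve of the planted 50-TF experiment, for the lambda plot
    from tfatlas.simulate import generate_consolidated_weights
    W, _ = generate_consolidated_weights(50, 4000, 5, 0.1, seed=1)
    cn = assoc.filter_regulatees(assoc.ConsolidatedNetwork("planted", W))
    rho, _ = assoc.spearman_tf_tf(cn)
    S = assoc.nearest_psd(rho)
    path = assoc.glasso_path(S, assoc.default_lambda_grid(S.to_numpy()))
    pd.DataFrame({"lambda": [p.lambda_ for p in path],
                  "density": [p.density for p in path]}).to_csv(
        adir / "sparsity_curve.tsv", sep="\t", index=False)
    print(f"written to {adir}")


if __name__ == "__main__":
    main()
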