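"""Generate the synthetic 9-state T cell atlas used by the whole analysis.

27 samples (9 states x 3 replicates), 600 genes of which 120 are TFs,
800 ATAC peaks, motif affinities for every TF, and 10 planted single-state
TFs per state at effect size 4. The bundle (expression, accessibility,
peaks as BED, gene models, motif table, design, planted truth) is written
under results/atlas/.
"""

from pathlib import Path

from tfatlas import io, simulate

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    atlas = simulate.generate_atlas(seed=seed)
    io.write_atlas(atlas, OUT / "atlas")
    n_planted = sum(len(v) for v in atlas.truth.planted_single_state.values())
    print(f"atlas: {atlas.expression.shape[0]} genes "
          f"({len(atlas.tfs)} TFs) x {len(atlas.samples)} samples, "
          f"{atlas.accessibility.shape[0]} peaks")
    print(f"planted: {n_planted} single-state TFs "
          f"({len(atlas.truth.planted_single_state)} states x 10), "
          f"effect size {atlas.truth.effect_size}")
    print(f"written to {OUT / 'atlas'}")


if __name__ == "__main__":
    main()
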