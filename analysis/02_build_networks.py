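"""Build one weighted, directed TF->gene regulatory network per sample.

Peaks are linked to genes by a 10 kb TSS window; each edge combines motif
affinity, peak accessibility, and TF/target expression (rank-normalized)
as a geometric mean. Edge lists are written under results/networks/.
"""

from pathlib import Path

import numpy as np

from tfatlas import grn, io

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    atlas = io.read_atlas(OUT / "atlas")
    networks = grn.build_all_grns(atlas, window_bp=10_000)
    netdir = OUT / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    sizes = []
    for sample, net in networks.items():
        io.write_network(net, netdir / sample)
        sizes.append(len(net.edges))
    first = networks[atlas.samples[0]]
    per_tf = first.edges.groupby("tf").size()
    print(f"{len(networks)} networks; edges/network "
          f"{np.mean(sizes):.0f} +/- {np.std(sizes):.0f}")
    print(f"sample {atlas.samples[0]}: each TF regulates "
          f"{per_tf.mean():.1f} genes on average "
          f"(min {per_tf.min()}, max {per_tf.max()})")
    print(f"written to {netdir}")


if __name__ == "__main__":
    main()
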