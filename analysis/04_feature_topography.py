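"""Where do the discriminative features live on the scalp?

Pools each participant's 20 best-ranked time-frequency/FAA features, tallies
them by region and hemisphere, and embeds one participant's feature rows
with UMAP for visual cluster inspection.

Writes results/pooled_feature_tally.csv, results/feature_topography.png,
results/umap_coords.csv and results/umap_embedding.png.
"""

import argparse
from pathlib import Path

import pandas as pd

from emodecode import (CVConfig, decode_cohort, embed_umap,
                       plot_feature_topography, pool_top_features,
                       reduced_study_config)
from emodecode.visualization import frontal_lr_ratio, plot_embedding

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--faa-effect", type=float, default=1.5)
    args = ap.parse_args()

    sim = reduced_study_config(seed=args.seed, faa_effect=args.faa_effect)
    decoding = decode_cohort(sim, CVConfig(seed=args.seed + 1013))
    montage = sim.montage

    pooled = pool_top_features(decoding.rankings,
                               decoding.features[0].descriptors, top_n=20)
    OUT.mkdir(exist_ok=True)
    fig, tally = plot_feature_topography(pooled, montage,
                                         path=str(OUT / "feature_topography.png"))
    tally.to_csv(OUT / "pooled_feature_tally.csv", index=False)
    left, right = frontal_lr_ratio(tally)
    n_pairs = sum(d.pair is not None for d in pooled)
    print(f"pooled {len(pooled)} features ({n_pairs} FAA pair features)")
    print(f"frontal single-channel tally left:right = {left}:{right}")
    print(tally.to_string(index=False))

    fa = decoding.features[0]
    coords = embed_umap(fa, seed=args.seed)
    pd.DataFrame({"umap1": coords[:, 0], "umap2": coords[:, 1],
                  "label": fa.labels, "trial": fa.groups}
                 ).to_csv(OUT / "umap_coords.csv", index=False)
    plot_embedding(coords, fa.labels, path=str(OUT / "umap_embedding.png"))
    print(f"\nUMAP embedding of participant 0 written "
          f"({fa.n_windows} windows)")


if __name__ == "__main__":
    main()
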