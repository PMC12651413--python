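#!/usr/bin/env python
"""Classify the three contrasts and partition the marker sets.

Reads the processed table from step 02, applies the |d| > 1 & p < 0.05
rule per feature for Organic (DO vs D), Variety (D vs PF) and Process
(PS vs PF), and writes the marker matrix, Venn partition, heatmap and a
recovery check against the simulated ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from tomarker.io import read_feature_table, to_log10
from tomarker.stats import CONTRASTS, build_marker_matrix, classify_contrast, render_heatmap, venn_partition

IN = Path("results/analysis/processed")
SIM = Path("results/analysis/sim")
OUT = Path("results/analysis/markers")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = to_log10(
        read_feature_table(IN / "intensities.csv", IN / "injections.csv", IN / "features.csv")
    )
    results = {c: classify_contrast(table, c) for c in CONTRASTS}
    for c, res in results.items():
        res.to_csv(OUT / f"comparison_{c.lower()}.tsv", sep="\t")
    matrix = build_marker_matrix(results)
    matrix.to_csv(OUT / "marker_matrix.tsv", sep="\t")
    part = venn_partition(matrix)
    (OUT / "venn_sizes.json").write_text(json.dumps(part.sizes(), indent=2))
    fig, _ = render_heatmap(matrix, path=str(OUT / "marker_heatmap.png"))
    import matplotlib.pyplot as plt

    plt.close(fig)

    print("discriminant compounds per contrast:",
          {k: len(v) for k, v in part.discriminant.items()})
    print("exclusive to one contrast:",
          {k: len(part.region(k)) for k in part.discriminant})

    truth = pd.read_csv(SIM / "ground_truth_labels.tsv", sep="\t", index_col=0)
    truth = truth.loc[truth.index.intersection(matrix.index)]
    agree = (matrix.loc[truth.index] == truth).all(axis=1).mean()
    for c in matrix.columns:
        inj = truth[c] != "="
        sens = (matrix.loc[truth.index[inj], c] == truth.loc[inj, c]).mean()
        fp = (matrix.loc[truth.index[~inj], c] != "=").mean()
        print(f"  {c}: sensitivity {sens:.2f}, false-label rate {fp:.3f}")
    print(f"rows fully matching ground truth: {agree:.1%}")


if __name__ == "__main__":
    main()
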