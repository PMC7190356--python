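#!/usr/bin/env python
"""Normalize the bulk time courses and fit the trajectory PCA.

Size-factor normalization (median-of-ratios), replicate averaging, the
mean-count >10 expression filter and log2(x+1), then PCA with samples as
observations.  Reports the variance captured per component and the number of
genes whose squared loadings carry 10% and 25% of the PC1 variance, and
writes scores, loadings and the selected gene lists under results/bulk/.
"""

from pathlib import Path

import pandas as pd

from dediff import (
    average_replicates,
    compute_size_factors,
    filter_by_mean_count,
    fit_pca,
    log_transform,
    normalize,
    select_top_contributors,
)
from dediff.io import read_count_matrix, write_normalized_matrix

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "bulk"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm = read_count_matrix(ROOT / "data" / "counts.tsv", ROOT / "data" / "samples.csv")
    factors = compute_size_factors(cm)
    avg = average_replicates(normalize(cm, factors))
    write_normalized_matrix(avg, OUT / "normalized_avg.tsv", OUT / "samples_avg.csv")

    logged = log_transform(filter_by_mean_count(avg, 10.0))
    model = fit_pca(logged, 3)
    model.scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
    model.loadings.to_csv(OUT / "pca_loadings.tsv", sep="\t")

    print(f"{len(logged.genes)} genes pass the mean-count filter")
    for k, vf in enumerate(model.variance_fraction, start=1):
        print(f"PC{k}: {100 * vf:.1f}% of variance")
    rows = []
    for fraction in (0.10, 0.25):
        sel = select_top_contributors(model, 1, fraction)
        rows.append((fraction, len(sel.genes), sel.achieved_fraction))
        pd.Series(sel.genes).to_csv(
            OUT / f"pc1_top_genes_{int(100 * fraction)}pct.txt",
            index=False, header=False,
        )
        print(
            f"{len(sel.genes)} genes carry {100 * sel.achieved_fraction:.1f}% "
            f"of PC1 variance (target {100 * fraction:.0f}%)"
        )
    pd.DataFrame(rows, columns=["fraction", "n_genes", "achieved"]).to_csv(
        OUT / "pc1_selection.csv", index=False
    )


if __name__ == "__main__":
    main()
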