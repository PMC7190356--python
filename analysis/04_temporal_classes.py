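#!/usr/bin/env python
"""Temporal classes of the top PC1 genes and transient inductions.

Z-scores the log2 profiles of the genes carrying 10% of PC1 variance,
clusters them (1 - Pearson correlation, average linkage) into temporal
classes, compares cluster composition with the planted archetypes, and
detects transiently induced genes in each dedifferentiation medium.
"""

from pathlib import Path

import pandas as pd

from dediff import detect_transient_induction, hier_cluster, zscore_profiles
from dediff.containers import NormalizedMatrix
from dediff.io import read_normalized_matrix, write_panel

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "clusters"
K = 6


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    avg = read_normalized_matrix(
        ROOT / "bulk" / "normalized_avg.tsv", ROOT / "bulk" / "samples_avg.csv"
    )
    import numpy as np

    top = pd.read_csv(
        ROOT / "bulk" / "pc1_top_genes_10pct.txt", header=None
    )[0].tolist()
    logged = NormalizedMatrix(
        np.log2(avg.values.loc[top] + 1), avg.samples, log2=True
    )
    profiles = zscore_profiles(logged)
    assignment = hier_cluster(profiles, k=K)
    assignment.labels.to_csv(OUT / "clusters.tsv", sep="\t", header=True)
    print(f"{len(assignment.labels)} top-PC1 genes cut into {assignment.k} classes")

    truth = pd.read_csv(
        ROOT / "data" / "truth_archetypes.csv", index_col=0
    )["archetype"]
    comp = pd.crosstab(assignment.labels, truth.loc[assignment.labels.index])
    comp.to_csv(OUT / "cluster_vs_archetype.csv")
    purity = (comp.max(axis=1) / comp.sum(axis=1)).mean()
    print(f"mean cluster purity against planted archetypes: {purity:.2f}")

    for cond in ("dediff-liquid", "dediff-bacteria"):
        transient = detect_transient_induction(avg, cond)
        write_panel(transient, OUT / f"transient_{cond}.tsv")
        print(f"{len(transient)} transiently induced genes in {cond}")


if __name__ == "__main__":
    main()
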