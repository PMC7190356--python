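#!/usr/bin/env python
"""Threshold gene panels, forward/reverse symmetry and the overlap null.

Classifies changing genes per medium, labels gene direction over the steep
trajectory windows (development 2-6 hr; dedifferentiation 0.5-4 hr liquid,
0.5-5 hr bacteria), computes the two symmetry fractions, builds the
aggregation-specific and early-induced panels, and runs the 10,000-draw
random-panel permutation test.  Tables land under results/panels/.
"""

from pathlib import Path

import pandas as pd

from dediff import (
    GenePanel,
    classify_changing_genes,
    define_aggregation_panel,
    define_early_induced,
    direction_over_window,
    overlap_permutation_test,
    symmetry_overlap,
)
from dediff.io import read_count_matrix, read_normalized_matrix, write_json_report, write_panel

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "panels"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    avg = read_normalized_matrix(
        ROOT / "bulk" / "normalized_avg.tsv", ROOT / "bulk" / "samples_avg.csv"
    )
    universe = read_count_matrix(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "samples.csv"
    ).genes

    for cond in ("dediff-liquid", "dediff-bacteria"):
        changing = classify_changing_genes(avg, cond)
        write_panel(changing, OUT / f"changing_{cond}.tsv", OUT / f"changing_{cond}.json")
        print(f"{len(changing)} genes changing during dedifferentiation in {cond}")

    directions = {
        "dev": direction_over_window(avg, "development", (2, 6)),
        "liquid": direction_over_window(avg, "dediff-liquid", (0.5, 4)),
        "bacteria": direction_over_window(avg, "dediff-bacteria", (0.5, 5)),
    }
    pd.DataFrame(directions).to_csv(OUT / "window_directions.csv")

    def picked(src, label):
        d = directions[src]
        return set(d.index[d == label])

    both_up = GenePanel("dediff_up_both", picked("liquid", "up") & picked("bacteria", "up"))
    both_down = GenePanel(
        "dediff_down_both", picked("liquid", "down") & picked("bacteria", "down")
    )
    sym_up = symmetry_overlap(both_up, GenePanel("dev_down", picked("dev", "down")))
    sym_down = symmetry_overlap(both_down, GenePanel("dev_up", picked("dev", "up")))
    print(
        f"of {sym_up.size} genes up in both media, "
        f"{100 * sym_up.fraction:.0f}% are down during development"
    )
    print(
        f"of {sym_down.size} genes down in both media, "
        f"{100 * sym_down.fraction:.0f}% are up during development"
    )

    aggregation = define_aggregation_panel(avg)
    early = define_early_induced(avg, "dediff-bacteria")
    write_panel(aggregation, OUT / "aggregation.tsv", OUT / "aggregation.json")
    write_panel(early, OUT / "early_induced_bacteria.tsv", OUT / "early_induced_bacteria.json")
    perm = overlap_permutation_test(
        aggregation, early, universe, n_permutations=10_000, seed=SEED, method="sample"
    )
    print(
        f"aggregation panel ({len(aggregation)} genes) vs early-induced: "
        f"observed overlap {100 * perm.observed_fraction:.0f}%, "
        f"null median {100 * perm.null_median_fraction:.0f}%, "
        f"p = {perm.empirical_p:.2g}"
    )
    write_json_report(
        {
            "symmetry": {
                "up_n": sym_up.size, "up_fraction": sym_up.fraction,
                "down_n": sym_down.size, "down_fraction": sym_down.fraction,
            },
            "overlap_test": {
                "panel_size": perm.panel_size,
                "observed_overlap": perm.observed_overlap,
                "observed_fraction": perm.observed_fraction,
                "null_median_fraction": perm.null_median_fraction,
                "empirical_p": perm.empirical_p,
                "n_permutations": perm.n_permutations,
                "seed": SEED,
            },
        },
        OUT / "summary.json",
    )


if __name__ == "__main__":
    main()
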