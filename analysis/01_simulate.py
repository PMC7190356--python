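#!/usr/bin/env python
"""Generate the synthetic study datasets and their planted truth.

Writes, under results/data/: the bulk time-course count matrix (five
conditions, two replicates), single-cell counts as an MTX triplet with cell
metadata, cell tracks, reporter traces, and the truth tables used by the
recovery analyses (02-06 read these files).
"""

from pathlib import Path

from dediff import (
    SyntheticConfig,
    generate_sc_counts,
    generate_timecourse,
    generate_traces,
    generate_tracks,
)
from dediff.io import (
    write_count_matrix,
    write_json_report,
    write_sc_mtx,
    write_traces,
    write_tracks,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_genes=2000, seed=SEED)

    cm, truth = generate_timecourse(cfg)
    write_count_matrix(cm, OUT / "counts.tsv", OUT / "samples.csv")
    truth.gene_archetype.to_csv(OUT / "truth_archetypes.csv", header=True)
    print(f"bulk: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} libraries")

    sc, sc_truth = generate_sc_counts(cfg)
    write_sc_mtx(sc, OUT / "sc")
    sc_truth.cell_fate.to_csv(OUT / "sc" / "truth_fates.csv", index_label="barcode")
    write_json_report(
        {
            "prestalk_markers": sc_truth.params["prestalk_markers"],
            "prespore_markers": sc_truth.params["prespore_markers"],
            "planted_merge_hour": sc_truth.planted_merge_hour,
        },
        OUT / "sc" / "truth_params.json",
    )
    print(f"single cell: {sc.counts.shape[0]} cells x {sc.counts.shape[1]} genes")

    tracks, tr_truth = generate_tracks(cfg)
    write_tracks(tracks, OUT / "tracks.csv")
    tr_truth.track_cluster.to_csv(OUT / "truth_track_clusters.csv", header=True)
    print(f"tracks: {len(tracks)} cells at 30 s frames")

    traces, trace_truth = generate_traces(SyntheticConfig(n_traces=100, seed=SEED))
    write_traces(traces, OUT / "traces.csv")
    trace_truth.planted_onsets.to_csv(OUT / "truth_onsets.csv")
    print(f"traces: {len(traces)} reporter time series")


if __name__ == "__main__":
    main()
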