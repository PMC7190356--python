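"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as gene x sample TSV with a sample-sheet CSV; single-cell
counts as an MTX triplet (matrix.mtx, features.tsv, barcodes.tsv); tracks,
traces and truth tables as CSV; panels as two-column TSV with a JSON
definition sidecar.  Read-after-write is the identity for every format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, GenePanel, InputError, NormalizedMatrix
from .single_cell import SCCountMatrix
from .tracks import CellTrack, ExpressionTrace


def _check_rectangular(path: Path, sep: str) -> None:
    with open(path) as fh:
        width = None
        for lineno, line in enumerate(fh, start=1):
            n = line.rstrip("\n").count(sep)
            if width is None:
                width = n
            elif n != width:
                raise InputError(f"{path}: ragged row at line {lineno}")


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts_path, samples_path = Path(counts_path), Path(samples_path)
    _check_rectangular(counts_path, "\t")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise InputError(f"{counts_path}: duplicate gene ids {dup}")
    samples = pd.read_csv(samples_path, index_col="sample_id")
    return CountMatrix(counts, samples)


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, index_label="sample_id")


def read_normalized_matrix(values_path, samples_path, log2: bool = False) -> NormalizedMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, index_col="sample_id")
    return NormalizedMatrix(values, samples, log2=log2)


def write_normalized_matrix(norm: NormalizedMatrix, values_path, samples_path) -> None:
    out = norm.values.copy()
    out.index.name = "gene_id"
    out.to_csv(values_path, sep="\t")
    norm.samples.to_csv(samples_path, index_label="sample_id")


def write_panel(panel: GenePanel, tsv_path, sidecar_path=None) -> None:
    genes = sorted(panel.genes)
    pd.DataFrame({"gene_id": genes, "panel": panel.name}).to_csv(
        tsv_path, sep="\t", index=False
    )
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"name": panel.name, "definition": panel.definition}, fh, indent=2)
            fh.write("\n")


def read_panel(tsv_path, name: str | None = None) -> GenePanel:
    table = pd.read_csv(tsv_path, sep="\t")
    if name is None:
        name = str(table["panel"].iloc[0]) if "panel" in table and len(table) else "panel"
    return GenePanel(name, frozenset(table["gene_id"]))


def write_sc_mtx(sc: SCCountMatrix, out_dir, meta_name: str = "cells.csv") -> None:
    """10x-style triplet: genes as matrix rows, cells as columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(sc.counts.to_numpy().T)
    spio.mmwrite(out_dir / "matrix.mtx", mat, field="integer")
    pd.Series(sc.counts.columns).to_csv(
        out_dir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(sc.counts.index).to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    sc.meta.to_csv(out_dir / meta_name, index_label="barcode")


def read_sc_mtx(in_dir, meta_name: str = "cells.csv") -> SCCountMatrix:
    in_dir = Path(in_dir)
    mat = spio.mmread(in_dir / "matrix.mtx").tocsr()
    features = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0]
    counts = pd.DataFrame(
        np.asarray(mat.todense()).T, index=barcodes, columns=features
    )
    counts.index.name = None
    meta = pd.read_csv(in_dir / meta_name, index_col="barcode")
    meta.index.name = None
    return SCCountMatrix(counts, meta)


def write_tracks(tracks: list[CellTrack], path) -> None:
    frames = []
    for tr in tracks:
        df = pd.DataFrame(
            {
                "track_id": tr.track_id,
                "frame": np.arange(len(tr.times)),
                "time_hr": tr.times,
                "x_um": tr.x,
                "y_um": tr.y,
                "divided": int(tr.divided),
                "division_time_hr": tr.division_time if tr.divided else np.nan,
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path) -> list[CellTrack]:
    table = pd.read_csv(path)
    tracks = []
    for tid, grp in table.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        division = None
        if "divided" in grp and bool(grp["divided"].iloc[0]):
            division = float(grp["division_time_hr"].iloc[0])
        tracks.append(
            CellTrack(
                str(tid),
                grp["time_hr"].to_numpy(),
                grp["x_um"].to_numpy(),
                grp["y_um"].to_numpy(),
                division_time=division,
            )
        )
    return tracks


def write_traces(traces: list[ExpressionTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "time_hr": tr.times,
                    "intensity": tr.intensity,
                    "division_time_hr": tr.division_time
                    if tr.division_time is not None
                    else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[ExpressionTrace]:
    table = pd.read_csv(path)
    traces = []
    for tid, grp in table.groupby("track_id", sort=False):
        grp = grp.sort_values("time_hr")
        division = grp["division_time_hr"].iloc[0] if "division_time_hr" in grp else np.nan
        traces.append(
            ExpressionTrace(
                str(tid),
                grp["time_hr"].to_numpy(),
                grp["intensity"].to_numpy(),
                division_time=None if pd.isna(division) else float(division),
            )
        )
    return traces


def write_json_report(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
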