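"""End-to-end pipeline driver: normalize -> average -> filter -> PCA ->
panels -> symmetry -> permutation test -> clustering.

Every threshold lives in :class:`PipelineConfig` with the study's stated
value as its default; a run writes each intermediate plus a manifest
recording inputs, parameters and seed, and is byte-identical when re-run
with the same configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import hier_cluster, zscore_profiles
from .containers import CountMatrix, InputError, NormalizedMatrix
from .gene_sets import (
    classify_changing_genes,
    define_aggregation_panel,
    define_early_induced,
    direction_over_window,
    overlap_permutation_test,
    symmetry_overlap,
)
from .io import (
    read_count_matrix,
    write_json_report,
    write_normalized_matrix,
    write_panel,
)
from .normalization import average_replicates, compute_size_factors, log_transform, normalize
from .pca import fit_pca, filter_by_mean_count, select_top_contributors
from .synthetic import BAC, LIQ, SyntheticConfig, generate_timecourse

STAGES = [
    "normalize",
    "average_replicates",
    "filter_and_log",
    "pca_and_selection",
    "panels",
    "symmetry",
    "permutation_test",
    "clustering",
]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a bulk-trajectory run."""

    counts_path: str | None = None
    samples_path: str | None = None
    out_dir: str = "results/pipeline"
    # when no input paths are given, simulate this design
    synthetic_n_genes: int = 2000
    seed: int = 0
    # thresholds (defaults are the study's stated values)
    mean_count_filter: float = 10.0
    changing_min_count: float = 100.0
    changing_min_abs_l2fc: float = 1.0
    fold: float = 2.0
    early_horizon_hr: float = 2.0
    early_min_rel_induction: float = 0.5
    n_permutations: int = 10_000
    loading_fraction_cluster: float = 0.10
    loading_fraction_general: float = 0.25
    pseudocount: float = 1.0
    dev_window: tuple = (2.0, 6.0)
    liquid_window: tuple = (0.5, 4.0)
    bacteria_window: tuple = (0.5, 5.0)
    n_components: int = 3
    n_clusters: int = 6

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dev_window", "liquid_window", "bacteria_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_counts(config: PipelineConfig) -> CountMatrix:
    if config.counts_path is not None:
        if config.samples_path is None:
            raise InputError("counts_path given without samples_path")
        for p in (config.counts_path, config.samples_path):
            if not Path(p).exists():
                raise InputError(f"input path does not exist: {p}")
        return read_count_matrix(config.counts_path, config.samples_path)
    cm, _ = generate_timecourse(
        SyntheticConfig(n_genes=config.synthetic_n_genes, seed=config.seed)
    )
    return cm


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict written to the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
    }
    report: dict = {}

    def _stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise InputError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        return result

    counts = _load_counts(config)

    def s_normalize() -> NormalizedMatrix:
        factors = compute_size_factors(counts)
        norm = normalize(counts, factors)
        factors.to_csv(out / "size_factors.csv", header=True)
        return norm

    norm = _stage("normalize", s_normalize)
    avg = _stage("average_replicates", lambda: average_replicates(norm))
    write_normalized_matrix(avg, out / "normalized_avg.tsv", out / "samples_avg.csv")

    def s_filter_log():
        filtered = filter_by_mean_count(avg, config.mean_count_filter)
        return filtered, log_transform(filtered, config.pseudocount)

    filtered, logged = _stage("filter_and_log", s_filter_log)

    def s_pca():
        model = fit_pca(logged, n_components=config.n_components)
        sel = select_top_contributors(model, 1, config.loading_fraction_cluster)
        model.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        model.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        return model, sel

    model, selection = _stage("pca_and_selection", s_pca)

    def s_panels():
        panels = {
            "changing_liquid": classify_changing_genes(
                avg, LIQ, config.changing_min_count, config.changing_min_abs_l2fc,
                config.pseudocount,
            ),
            "changing_bacteria": classify_changing_genes(
                avg, BAC, config.changing_min_count, config.changing_min_abs_l2fc,
                config.pseudocount,
            ),
            "aggregation": define_aggregation_panel(avg, config.fold),
            "early_induced_bacteria": define_early_induced(
                avg, BAC, config.early_horizon_hr, config.early_min_rel_induction,
                config.pseudocount,
            ),
            "early_induced_liquid": define_early_induced(
                avg, LIQ, config.early_horizon_hr, config.early_min_rel_induction,
                config.pseudocount,
            ),
        }
        for key, panel in panels.items():
            write_panel(panel, out / f"panel_{key}.tsv", out / f"panel_{key}.json")
        return panels

    panels = _stage("panels", s_panels)

    def s_symmetry():
        from .containers import GenePanel

        directions = {
            "dev": direction_over_window(avg, "development", config.dev_window, config.fold, config.pseudocount),
            "liquid": direction_over_window(avg, LIQ, config.liquid_window, config.fold, config.pseudocount),
            "bacteria": direction_over_window(avg, BAC, config.bacteria_window, config.fold, config.pseudocount),
        }

        def _panel(tag, src, label):
            d = directions[src]
            return GenePanel(tag, frozenset(d.index[d == label]))

        dediff_up = GenePanel(
            "dediff_up_both",
            _panel("l", "liquid", "up").genes & _panel("b", "bacteria", "up").genes,
        )
        dediff_down = GenePanel(
            "dediff_down_both",
            _panel("l", "liquid", "down").genes & _panel("b", "bacteria", "down").genes,
        )
        dev_up = _panel("dev_up", "dev", "up")
        dev_down = _panel("dev_down", "dev", "down")
        up_stat = symmetry_overlap(dediff_up, dev_down)
        down_stat = symmetry_overlap(dediff_down, dev_up)
        return {
            "dediff_up_both": len(dediff_up),
            "dediff_up_dev_down_overlap": up_stat.overlap,
            "dediff_up_dev_down_fraction": up_stat.fraction,
            "dediff_down_both": len(dediff_down),
            "dediff_down_dev_up_overlap": down_stat.overlap,
            "dediff_down_dev_up_fraction": down_stat.fraction,
        }

    report["symmetry"] = _stage("symmetry", s_symmetry)

    def s_permtest():
        result = overlap_permutation_test(
            panels["aggregation"],
            panels["early_induced_bacteria"],
            counts.genes,
            n_permutations=config.n_permutations,
            seed=config.seed,
            method="sample",
        )
        return {
            "observed_overlap": result.observed_overlap,
            "panel_size": result.panel_size,
            "observed_fraction": result.observed_fraction,
            "null_median_fraction": result.null_median_fraction,
            "empirical_p": result.empirical_p,
            "n_permutations": result.n_permutations,
        }

    report["permutation_test"] = _stage("permutation_test", s_permtest)

    def s_cluster():
        top = logged.values.loc[selection.genes]
        profiles = zscore_profiles(
            NormalizedMatrix(top, logged.samples, log2=True)
        )
        k = min(config.n_clusters, profiles.values.shape[0])
        assignment = hier_cluster(profiles, k=k)
        assignment.labels.to_csv(out / "clusters.tsv", sep="\t", header=True)
        return {"n_genes_clustered": int(len(assignment.labels)), "k": assignment.k}

    report["clustering"] = _stage("clustering", s_cluster)

    report["pca"] = {
        "n_genes_filtered": int(len(filtered.genes)),
        "variance_fraction": model.variance_fraction.tolist(),
        "pc1_selected_genes": len(selection.genes),
        "pc1_achieved_fraction": selection.achieved_fraction,
    }
    report["panels"] = {k: len(v) for k, v in panels.items()}

    write_json_report(manifest, out / "manifest.json")
    write_json_report(report, out / "report.json")
    return report
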