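"""Core in-memory containers shared across the pipeline.

A bulk experiment is a gene x sample count table plus a sample sheet with one
row per sequencing library (condition, time in hours, replicate).  All
downstream matrices keep pandas labelling so gene/sample identity survives
filtering, averaging and transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class InvalidConfigError(PipelineError, ValueError):
    """A configuration value violates its contract."""


class EstimationError(PipelineError, RuntimeError):
    """A statistical estimate is undefined for the given input."""


class InputError(PipelineError, ValueError):
    """An input table violates its format contract."""


SAMPLE_COLUMNS = ("condition", "time_hr", "replicate")


def _check_sample_sheet(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise InputError(f"sample sheet missing columns: {missing}")
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()].tolist()
        raise InputError(f"duplicate sample ids: {dup}")
    if (samples["time_hr"] < 0).any():
        raise InputError("negative time_hr in sample sheet")


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a sample sheet.

    ``counts``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition``, ``time_hr``, ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dup}")
        _check_sample_sheet(self.samples)
        unknown = [s for s in self.counts.columns if s not in self.samples.index]
        if unknown:
            raise InputError(f"samples absent from sample sheet: {unknown}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise InputError("non-finite counts")
        if (vals < 0).any():
            raise InputError("negative counts")
        # keep the sheet aligned to the count columns
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def subset_condition(self, condition: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["condition"] == condition]
        return CountMatrix(self.counts[list(keep)].copy(), self.samples.loc[keep].copy())


@dataclass
class NormalizedMatrix:
    """Real-valued gene x sample matrix carrying its provenance.

    ``size_factors`` records the per-sample divisors applied (None before
    normalization); ``log2`` / ``log10`` flag whether a log transform has been
    applied, so threshold rules can refuse to run on the wrong scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None
    log2: bool = False
    dropped_genes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sample_sheet(self.samples)
        unknown = [s for s in self.values.columns if s not in self.samples.index]
        if unknown:
            raise InputError(f"samples absent from sample sheet: {unknown}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_condition(self, condition: str) -> "NormalizedMatrix":
        keep = self.samples.index[self.samples["condition"] == condition]
        sf = None if self.size_factors is None else self.size_factors.loc[keep]
        return NormalizedMatrix(
            self.values[list(keep)].copy(),
            self.samples.loc[keep].copy(),
            size_factors=sf,
            log2=self.log2,
        )

    def condition_timecourse(self, condition: str) -> pd.DataFrame:
        """Gene x time table for one condition (columns sorted by time).

        Requires replicate-averaged input (one sample per timepoint).
        """
        sub = self.subset_condition(condition)
        times = sub.samples["time_hr"]
        if times.duplicated().any():
            raise InputError(
                f"condition {condition!r} has replicate samples; average replicates first"
            )
        order = times.sort_values().index
        tc = sub.values[list(order)].copy()
        tc.columns = times.loc[order].to_numpy(dtype=float)
        return tc


@dataclass
class GenePanel:
    """A named gene set plus the rule and parameters that produced it."""

    name: str
    genes: frozenset
    definition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.genes
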