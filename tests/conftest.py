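import numpy as np
import pandas as pd
import pytest

from dediff.containers import CountMatrix, NormalizedMatrix


def make_count_matrix(values, conditions=None, times=None, replicates=None) -> CountMatrix:
    """Small CountMatrix from a 2-D array; metadata defaults to one condition."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    sids = [f"s{j}" for j in range(n_samples)]
    samples = pd.DataFrame(
        {
            "condition": conditions or ["c"] * n_samples,
            "time_hr": times if times is not None else list(range(n_samples)),
            "replicate": replicates or [1] * n_samples,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return CountMatrix(pd.DataFrame(values, index=genes, columns=sids), samples)


def make_timecourse(values, condition="dediff-bacteria", times=None) -> NormalizedMatrix:
    """Replicate-averaged normalized matrix for one condition."""
    values = np.asarray(values, dtype=float)
    n_genes, n_t = values.shape
    times = list(times) if times is not None else list(range(n_t))
    sids = [f"{condition}_t{t:g}" for t in times]
    samples = pd.DataFrame(
        {"condition": condition, "time_hr": times, "replicate": 1},
        index=pd.Index(sids, name="sample_id"),
    )
    genes = [f"g{i}" for i in range(n_genes)]
    return NormalizedMatrix(pd.DataFrame(values, index=genes, columns=sids), samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
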