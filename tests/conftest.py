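import numpy as np
import pytest

from proteoconcord.quantio import LOG2, RAW, QuantMatrix, SampleMetadata


def make_matrix(values, mask=None, scale=RAW, prefix="P", sample_prefix="S"):
    """Build a QuantMatrix from a plain array; None entries become missing."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    if mask is None:
        mask = ~np.isnan(arr)
    n, m = arr.shape
    return QuantMatrix(
        protein_ids=[f"{prefix}{i}" for i in range(n)],
        sample_ids=[f"{sample_prefix}{j}" for j in range(m)],
        values=arr,
        mask=np.asarray(mask, dtype=bool),
        scale=scale,
    )


def make_metadata(cohorts, groups=None, sample_prefix="S"):
    """Metadata for samples S0..Sn-1 given per-sample cohort (and group) labels."""
    if groups is None:
        groups = ["G"] * len(cohorts)
    return [
        SampleMetadata(sample_id=f"{sample_prefix}{j}", cohort=c, group=g)
        for j, (c, g) in enumerate(zip(cohorts, groups))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_log2_matrix(rng):
    """Complete 20x10 log2-scale matrix, two cohorts of 5 samples each."""
    values = rng.normal(20.0, 1.0, size=(20, 10))
    matrix = make_matrix(values, scale=LOG2)
    metadata = make_metadata(["A"] * 5 + ["B"] * 5)
    return matrix, metadata
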