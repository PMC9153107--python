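import numpy as np
import pandas as pd
import pytest

from hyporank.ranks import RankPercentileMatrix
from hyporank.simulate import LabeledDataset


def percentile_dataset(X, labels, genes=None, samples=None) -> LabeledDataset:
    """Build a LabeledDataset in percentile space from a genes-x-samples array."""
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    samples = samples or [f"s{i}" for i in range(X.shape[1])]
    rpm = RankPercentileMatrix(pd.DataFrame(X, index=genes, columns=samples))
    return LabeledDataset(
        matrix=rpm, labels=pd.Series(list(labels), index=samples, name="label")
    )


@pytest.fixture
def separable_1d():
    """One informative feature, perfectly separable at percentile 50."""
    return percentile_dataset(
        [[10.0, 20.0, 80.0, 90.0]],
        ["normoxic", "normoxic", "hypoxic", "hypoxic"],
        genes=["gA"],
    )
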