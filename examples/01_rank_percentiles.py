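"""Rank percentiles: the normalization-free sample representation.

Builds a tiny counts matrix, converts it to within-sample rank percentiles
(100 = most expressed gene of the sample, 0 = least) and shows that any
strictly increasing re-expression of the counts — CPM scaling, log
transform — leaves the percentiles bitwise unchanged.  This is why a
single isolated sample can be classified without reference samples or
between-sample normalization.
"""

import numpy as np
import pandas as pd

from hyporank import ExpressionMatrix, rank_percentile

counts = pd.DataFrame(
    {
        "sample_1": [5, 1, 0, 0, 42],
        "sample_2": [10, 200, 3, 7, 0],
    },
    index=["EGLN1", "NDRG1", "ANKRD37", "PFKFB3", "MIR210HG"],
)
matrix = ExpressionMatrix(counts.astype(float))
rpm = rank_percentile(matrix)

print("counts:")
print(counts)
print("\nrank percentiles (ties at zero share one percentile):")
print(rpm.data.round(2))

cpm = ExpressionMatrix(1e6 * counts / counts.sum(axis=0))
logged = ExpressionMatrix(np.log1p(counts.astype(float)))
assert (rank_percentile(cpm).values == rpm.values).all()
assert (rank_percentile(logged).values == rpm.values).all()
print("\nCPM-scaled and log1p-transformed counts give identical percentiles:")
print("rank percentiles are invariant under any strictly increasing transform.")
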