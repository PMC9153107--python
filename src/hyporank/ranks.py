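"""Within-sample rank-percentile representation of expression matrices.

Every classifier in this package consumes rank percentiles rather than raw
abundances: per sample, genes are ranked by expression (average competition
ranks, so ties share a rank) and rescaled so the most expressed gene sits at
percentile 100 and the least at 0.  Because ranks are invariant under any
strictly increasing per-sample transform, counts, pseudocounts, CPM or TPM
all yield the same representation — no between-sample normalization is
needed, and a single isolated sample can be classified without a reference
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "RankPercentileMatrix",
    "rank_percentile",
    "subset_genes",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups[:10]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene-by-sample abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with gene IDs as the index and sample IDs as columns.
        Values may be counts, pseudocounts, CPM or any unit that is a
        strictly increasing function of abundance; only within-sample
        ordering matters downstream.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        if self.data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 sample")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains NaN")
        if (values < 0).any():
            gene, sample = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at gene "
                f"{self.data.index[gene]!r}, sample {self.data.columns[sample]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class RankPercentileMatrix:
    """Per-sample gene rank percentiles in [0, 100].

    Columns anchored so the most expressed gene of a sample is 100 and the
    least is 0 whenever those extremes are untied (a tied extreme shares
    the averaged rank of its tie group, pulling it off the anchor — e.g.
    genes tied at zero counts all share one low percentile).
    ``flagged_samples``
    lists samples whose input column was constant (for example blank spatial
    spots); their percentiles are all 50 and carry no ranking information.
    """

    data: pd.DataFrame
    flagged_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1:
            raise ValueError("rank percentile matrix needs at least 1 gene")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and ((values < 0) | (values > 100)).any():
            raise ValueError("percentiles must lie in [0, 100]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def rank_percentile(matrix: ExpressionMatrix) -> RankPercentileMatrix:
    """Convert abundances to within-sample rank percentiles.

    Per sample (column), genes receive average competition ranks *r*
    (smallest value gets rank 1, ties get the mean of the ranks they cover)
    and percentile ``100 * (r - 1) / (G - 1)`` where *G* is the number of
    genes, so the top gene scores exactly 100 and the bottom gene 0.

    Percentiles are computed over all genes present in ``matrix``; restrict
    to a signature *after* ranking (see :func:`subset_genes`), because
    thresholds learned on full-transcriptome ranks only apply to
    full-transcriptome ranks.

    A constant column (e.g. an empty spatial spot) yields all-50 percentiles
    and is flagged with a warning rather than raising, so spatial runs do
    not abort on blank spots.
    """
    values = matrix.values.astype(float)
    n_genes = values.shape[0]
    # rankdata: average method gives mean of covered ranks for ties
    ranks = rankdata(values, method="average", axis=0)
    percentiles = 100.0 * (ranks - 1.0) / (n_genes - 1.0)
    constant = (values.max(axis=0) - values.min(axis=0)) == 0
    flagged: tuple[str, ...] = ()
    if constant.any():
        flagged = tuple(np.asarray(matrix.sample_ids)[constant])
        warnings.warn(
            f"{len(flagged)} sample(s) have constant expression "
            f"(all percentiles set to 50): {list(flagged)[:5]}",
            UserWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(percentiles, index=matrix.data.index, columns=matrix.data.columns)
    return RankPercentileMatrix(out, flagged_samples=flagged)


def subset_genes(
    rpm: RankPercentileMatrix,
    genes: list[str],
    on_missing: str = "error",
) -> tuple[RankPercentileMatrix, list[str]]:
    """Restrict a percentile matrix to a gene signature.

    Percentiles are **not** recomputed: they keep referring to the full
    ranking of the original matrix.  Rows are returned in the requested
    order.

    Parameters
    ----------
    on_missing:
        ``"error"`` raises naming the first absent gene, ``"drop"`` and
        ``"flag"`` keep going; missing genes are always reported in the
        second return value.

    Returns
    -------
    (subset, missing):
        The restricted matrix and the list of requested genes that were
        absent.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if on_missing not in {"error", "drop", "flag"}:
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    present_index = rpm.data.index
    missing = [g for g in genes if g not in present_index]
    if missing and on_missing == "error":
        raise KeyError(f"gene {missing[0]!r} not present in matrix")
    if missing and on_missing == "flag":
        warnings.warn(
            f"{len(missing)} requested gene(s) absent: {missing[:5]}",
            UserWarning,
            stacklevel=2,
        )
    kept = [g for g in genes if g not in missing]
    if not kept:
        raise ValueError("no requested genes present in matrix")
    sub = RankPercentileMatrix(rpm.data.loc[kept], flagged_samples=rpm.flagged_samples)
    return sub, missing
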