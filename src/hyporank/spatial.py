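"""Per-spot classification of spatial transcriptomics sections.

Each capture spot is treated as one sample: its counts are converted to
rank percentiles over all genes in the matrix (never a signature subset)
and classified by the tree ensemble.  Blank spots — all-zero columns with
no ranking information — are flagged and reported with label "NA".
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from hyporank.ensemble import TreeEnsemble, ensemble_predict
from hyporank.ranks import ExpressionMatrix, rank_percentile
from hyporank.simulate import LabeledDataset

__all__ = ["classify_spots"]


def classify_spots(
    ensemble: TreeEnsemble,
    spots: Union[ExpressionMatrix, LabeledDataset],
    threshold: float = 0.5,
    coords: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Classify every spot of a spatial expression matrix.

    Parameters
    ----------
    ensemble:
        Tree ensemble, already filtered for feature availability.
    spots:
        Genes-by-spots counts (e.g. from a 10x triplet directory) or a
        simulated spatial dataset carrying its own coordinates.
    coords:
        Optional per-barcode x/y table; overrides coordinates attached to
        a simulated dataset.

    Returns
    -------
    DataFrame indexed by barcode with columns ``x``/``y`` (when known),
    ``mean_probability``, ``label`` ("normoxic"/"hypoxic", or "NA" for
    blank spots), and ``n_trees_used``.
    """
    if isinstance(spots, LabeledDataset):
        matrix = spots.matrix
        if coords is None:
            coords = spots.coords
        if not isinstance(matrix, ExpressionMatrix):
            raise TypeError("spatial classification expects raw counts, not percentiles")
    else:
        matrix = spots
    if matrix.shape[1] == 0:
        raise ValueError("spatial matrix has zero spots")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # blank spots flagged below
        rpm = rank_percentile(matrix)
    result = ensemble_predict(ensemble, rpm, threshold=threshold)

    table = result.frame()
    blank = list(rpm.flagged_samples)
    if blank:
        warnings.warn(
            f"{len(blank)} blank spot(s) labeled NA: {blank[:5]}",
            UserWarning,
            stacklevel=2,
        )
        table.loc[blank, "label"] = "NA"
    table["blank"] = False
    if blank:
        table.loc[blank, "blank"] = True
    if coords is not None:
        table = table.join(coords.reindex(table.index))
        ordered = ["x", "y", "mean_probability", "label", "n_trees_used", "blank"]
        table = table[[c for c in ordered if c in table.columns]]
    table.index.name = "barcode"
    return table
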