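"""Random-forest feature selection by permutation importance (MDA).

The forest is not the final classifier — it ranks candidate genes.  Trees
are grown on bootstrap resamples with a random subset of genes considered
at every split; a gene's importance is the mean decrease in out-of-bag
(OOB) accuracy when its values are permuted, averaged first over the trees
of a forest and then over many forests, each grown on a fresh 70% resample
of the cohort.  Genes whose mean MDA exceeds a threshold (default 4
accuracy points) form the signature used for mass tree generation.

MDA is reported as the *raw* mean accuracy decrease in percentage points
(not scaled by its SD), so the selection threshold reads directly as
accuracy points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hyporank.cart import (
    CompiledTree,
    DecisionTree,
    TreeTrainParams,
    _gini,
    _grow,
    _percentile_frame,
)
from hyporank.simulate import HYPOXIC, LabeledDataset

__all__ = [
    "ForestParams",
    "RandomForest",
    "fit_forest",
    "permutation_importance",
    "select_features",
    "tune_hyperparameters",
]

# forest trees are grown essentially to purity, randomForest-style
_FOREST_TREE_PARAMS = TreeTrainParams(
    min_samples_split=2, min_leaf=1, max_depth=50, complexity_threshold=0.0
)


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters.

    ``features_per_split`` genes are drawn uniformly at every node (mtry);
    defaults (10 features, 200 trees) are the values selected by
    cross-validation for the hypoxia signature task.
    """

    n_trees: int = 200
    features_per_split: int = 10
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.features_per_split < 1:
            raise ValueError("features_per_split must be >= 1")


class RandomForest:
    """A fitted forest with recorded out-of-bag indices per tree."""

    def __init__(
        self,
        trees: list[DecisionTree],
        compiled: list[CompiledTree],
        oob_indices: list[np.ndarray],
        genes: list[str],
        params: ForestParams,
    ):
        self.trees = trees
        self._compiled = compiled
        self.oob_indices = oob_indices
        self.genes = genes
        self.params = params

    def vote_share(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting hypoxic per row of ``X`` (samples x genes)."""
        votes = np.zeros(X.shape[0])
        for ct in self._compiled:
            votes += ct.predict(X) > 0.5
        return votes / len(self._compiled)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote class (True = hypoxic) per sample."""
        return self.vote_share(X) > 0.5

    def oob_votes(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample hypoxic OOB vote counts and coverage counts."""
        n = X.shape[0]
        votes = np.zeros(n)
        covered = np.zeros(n)
        for ct, oob in zip(self._compiled, self.oob_indices):
            if oob.size == 0:
                continue
            votes[oob] += ct.predict(X[oob]) > 0.5
            covered[oob] += 1
        return votes, covered

    def oob_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        """Majority-vote accuracy on out-of-bag samples (NaN if none covered)."""
        votes, covered = self.oob_votes(X)
        mask = covered > 0
        if not mask.any():
            return float("nan")
        pred = votes[mask] / covered[mask] > 0.5
        return float(np.mean(pred == y[mask]))


def _dataset_arrays(data: LabeledDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    frame = _percentile_frame(data)
    X = np.ascontiguousarray(frame.to_numpy().T)
    y = data.labels.to_numpy() == HYPOXIC
    return X, y, list(frame.index)


def _fit_forest_arrays(
    X: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    params: ForestParams,
    rng: np.random.Generator,
    tree_params: TreeTrainParams = _FOREST_TREE_PARAMS,
) -> RandomForest:
    n = X.shape[0]
    all_cols = np.array(sorted(range(len(genes)), key=genes.__getitem__), dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mtry = params.features_per_split
    trees: list[DecisionTree] = []
    compiled: list[CompiledTree] = []
    oob_list: list[np.ndarray] = []
    for t in range(params.n_trees):
        if params.bootstrap:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
        else:
            idx = np.arange(n)
            oob = np.array([], dtype=int)
        Xb, yb = X[idx], y[idx]
        root_gini = _gini(int(yb.sum()), yb.size)
        root = _grow(
            Xb, yb, genes, tree_params, Xb.shape[0], root_gini, 0, rng, mtry, all_cols
        )
        tree = DecisionTree(root=root, tree_id=str(t))
        trees.append(tree)
        compiled.append(CompiledTree(tree, gene_pos))
        oob_list.append(oob)
    return RandomForest(trees, compiled, oob_list, genes, params)


def fit_forest(
    data: LabeledDataset,
    params: ForestParams = ForestParams(),
    tree_params: TreeTrainParams = _FOREST_TREE_PARAMS,
) -> RandomForest:
    """Grow a random forest on a labeled dataset in percentile space."""
    X, y, genes = _dataset_arrays(data)
    if params.features_per_split > len(genes):
        raise ValueError(
            f"features_per_split={params.features_per_split} exceeds "
            f"{len(genes)} candidate genes"
        )
    if y.all() or not y.any():
        raise ValueError("forest training requires both classes present")
    rng = np.random.default_rng(params.seed)
    return _fit_forest_arrays(X, y, genes, params, rng, tree_params)


def _forest_mda(
    forest: RandomForest, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene mean decrease in OOB accuracy for one forest (fractions)."""
    n_genes = len(forest.genes)
    mda = np.zeros(n_genes)
    n_trees = len(forest.trees)
    for ct, oob in zip(forest._compiled, forest.oob_indices):
        if oob.size == 0:
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        base = np.mean((ct.predict(Xo) > 0.5) == yo)
        used = np.unique(ct.feature[ct.feature >= 0])
        for g in used:
            original = Xo[:, g].copy()
            Xo[:, g] = original[rng.permutation(oob.size)]
            perm = np.mean((ct.predict(Xo) > 0.5) == yo)
            Xo[:, g] = original
            mda[g] += base - perm
    return mda / n_trees


def permutation_importance(
    data: LabeledDataset,
    params: ForestParams = ForestParams(),
    n_iterations: int = 1000,
    subsample: float = 0.7,
) -> pd.DataFrame:
    """Mean decrease in accuracy per gene across repeated forests.

    Each iteration draws ``subsample`` (70% by default) of the samples
    without replacement, grows a forest, and measures per gene the drop in
    per-tree OOB accuracy when the gene's values are permuted among each
    tree's OOB samples.  Trees that never test a gene contribute zero for
    it (permuting an unused feature cannot change routing), so a constant
    or irrelevant gene scores ~0.

    Returns a DataFrame indexed by gene with ``mean_mda`` and ``sd_mda`` in
    accuracy percentage points and ``n_iter``, sorted by decreasing mean.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0.0 < subsample <= 1.0:
        raise ValueError("subsample must lie in (0, 1]")
    X, y, genes = _dataset_arrays(data)
    if params.features_per_split > len(genes):
        raise ValueError("features_per_split exceeds candidate gene count")
    n = X.shape[0]
    n_sub = max(2, int(round(subsample * n)))
    rng = np.random.default_rng(params.seed)

    per_iter = np.zeros((n_iterations, len(genes)))
    for it in range(n_iterations):
        for _ in range(100):
            idx = rng.choice(n, size=n_sub, replace=False)
            ys = y[idx]
            if ys.any() and not ys.all():
                break
        else:
            raise RuntimeError("could not draw a two-class subsample")
        forest = _fit_forest_arrays(X[idx], ys, genes, params, rng)
        per_iter[it] = _forest_mda(forest, X[idx], ys, rng)

    per_iter *= 100.0  # accuracy percentage points
    table = pd.DataFrame(
        {
            "mean_mda": per_iter.mean(axis=0),
            "sd_mda": per_iter.std(axis=0, ddof=1) if n_iterations > 1 else 0.0,
            "n_iter": n_iterations,
        },
        index=pd.Index(genes, name="gene"),
    )
    return table.sort_values("mean_mda", ascending=False)


def select_features(
    importance: pd.DataFrame,
    mda_threshold: float = 4.0,
    top_k: Optional[int] = None,
) -> list[str]:
    """Genes with mean MDA strictly above the threshold, best first.

    ``top_k`` additionally caps the list at the k most important genes —
    useful when many partially redundant markers dilute each other's raw
    MDA and an absolute threshold calibrated on other data does not carry
    over.
    """
    if importance.empty:
        raise ValueError("importance table is empty")
    kept = importance[importance["mean_mda"] > mda_threshold]
    if kept.empty:
        warnings.warn(
            f"no gene exceeds MDA threshold {mda_threshold}", UserWarning, stacklevel=2
        )
    ordered = list(kept.sort_values("mean_mda", ascending=False).index)
    return ordered[:top_k] if top_k is not None else ordered


def tune_hyperparameters(
    data: LabeledDataset,
    features_per_split_grid: Sequence[int],
    n_trees_grid: Sequence[int],
    n_cv: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[ForestParams, pd.DataFrame]:
    """Pick forest hyperparameters by cross-validation accuracy.

    Every (mtry, n_trees) grid point is scored by mean holdout accuracy
    over ``n_cv`` random 70/30 splits; the argmax is returned, with ties
    going to the smaller model (fewer trees, then fewer features).
    """
    if not features_per_split_grid or not n_trees_grid:
        raise ValueError("hyperparameter grid must be non-empty")
    X, y, genes = _dataset_arrays(data)
    for mtry in features_per_split_grid:
        if not 1 <= mtry <= len(genes):
            raise ValueError(f"features_per_split={mtry} invalid for {len(genes)} genes")
    for n_trees in n_trees_grid:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("train_frac leaves an empty train or holdout set")
    rng = np.random.default_rng(seed)
    # shared splits across grid points for a paired comparison
    splits = []
    for _ in range(n_cv):
        for _ in range(100):
            perm = rng.permutation(n)
            if y[perm[:n_train]].any() and not y[perm[:n_train]].all():
                splits.append(perm)
                break
        else:
            raise RuntimeError("could not draw a two-class training split")

    rows = []
    for mtry, n_trees in product(features_per_split_grid, n_trees_grid):
        params = ForestParams(n_trees=n_trees, features_per_split=mtry, seed=seed)
        accs = []
        for perm in splits:
            tr, ho = perm[:n_train], perm[n_train:]
            forest = _fit_forest_arrays(X[tr], y[tr], genes, params, rng)
            accs.append(np.mean(forest.predict(X[ho]) == y[ho]))
        rows.append(
            {
                "features_per_split": mtry,
                "n_trees": n_trees,
                "mean_accuracy": float(np.mean(accs)),
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_accuracy", "n_trees", "features_per_split"],
        ascending=[False, True, True],
    ).iloc[0]
    chosen = ForestParams(
        n_trees=int(best["n_trees"]),
        features_per_split=int(best["features_per_split"]),
        seed=seed,
    )
    return chosen, table
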