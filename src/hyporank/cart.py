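"""Binary classification trees on rank percentiles (CART, Gini impurity).

These small trees are the classifier proper: each internal node compares one
gene's within-sample rank percentile against a threshold ("percentile >=
threshold" follows the high branch) and each leaf carries the hypoxia
probability observed in the training samples that reached it.  Induction is
greedy recursive partitioning minimizing weighted Gini impurity, with
thresholds placed at midpoints between consecutive distinct observed
percentiles.

Training is fully deterministic: split ties are broken by lexicographically
smallest gene ID, then by lowest threshold, and samples exactly at a
threshold are routed to the high branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from hyporank.ranks import RankPercentileMatrix
from hyporank.simulate import HYPOXIC, LabeledDataset

__all__ = [
    "Leaf",
    "Split",
    "TreeTrainParams",
    "DecisionTree",
    "fit_tree",
    "predict_tree",
    "render_tree",
]

_TIE_TOL = 1e-12


@dataclass
class Leaf:
    """Terminal node: hypoxia probability and training-sample fraction."""

    probability: float
    fraction: float
    extra: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        # class is H iff probability > 0.5 (strict), per the default rule
        return "H" if self.probability > 0.5 else "N"


@dataclass
class Split:
    """Internal node: gene + percentile threshold; >= goes to ``high``."""

    gene: str
    threshold: float
    low: "Node"
    high: "Node"
    probability: float = float("nan")
    fraction: float = float("nan")
    extra: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return "H" if self.probability > 0.5 else "N"


Node = Union[Leaf, Split]


@dataclass(frozen=True)
class TreeTrainParams:
    """Stopping and regularization controls for tree induction.

    Defaults mirror common CART practice (rpart-like) and yield the shallow
    3-5-gene trees the method relies on: nodes with fewer than
    ``min_samples_split`` samples are not split, children smaller than
    ``min_leaf`` are rejected, depth is capped, and a split must reduce the
    tree's total Gini impurity by at least ``complexity_threshold`` times
    the root impurity.
    """

    min_samples_split: int = 20
    min_leaf: int = 7
    max_depth: int = 5
    complexity_threshold: float = 0.01
    feature_subset: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.complexity_threshold < 0:
            raise ValueError("complexity_threshold must be >= 0")


@dataclass
class DecisionTree:
    """A fitted percentile-threshold classification tree."""

    root: Node
    tree_id: str = ""
    metadata: dict = field(default_factory=dict)

    def genes(self) -> tuple[str, ...]:
        """Sorted unique gene IDs referenced by any split."""
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, Split):
                out.add(node.gene)
                walk(node.low)
                walk(node.high)

        walk(self.root)
        return tuple(sorted(out))

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if isinstance(node, Leaf):
                return 1
            return count(node.low) + count(node.high)

        return count(self.root)

    def depth(self) -> int:
        def d(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(d(node.low), d(node.high))

        return d(self.root)


# ---------------------------------------------------------------------------
# induction


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _best_split(
    X: np.ndarray, y: np.ndarray, cols: np.ndarray, min_leaf: int
) -> Optional[tuple[int, float, float]]:
    """Exhaustive Gini scan over (feature, midpoint-threshold) candidates.

    Returns ``(column, threshold, weighted_child_gini)`` for the minimizing
    split, ties broken by the order of ``cols`` then ascending threshold, or
    None if no valid split exists.  ``cols`` must already be in gene-ID
    lexicographic order for the documented tie-break.
    """
    n = X.shape[0]
    if n < 2 * min_leaf:
        return None
    sub = X[:, cols]
    order = np.argsort(sub, axis=0, kind="stable")
    xs = np.take_along_axis(sub, order, axis=0)
    ys = y[order]
    pos_left = np.cumsum(ys, axis=0)[:-1].astype(float)  # (n-1, f)
    total_pos = float(y.sum())
    n_left = np.arange(1, n, dtype=float)[:, None]
    n_right = n - n_left
    pl = pos_left / n_left
    pr = (total_pos - pos_left) / n_right
    gini_left = 1.0 - pl**2 - (1.0 - pl) ** 2
    gini_right = 1.0 - pr**2 - (1.0 - pr) ** 2
    weighted = (n_left * gini_left + n_right * gini_right) / n
    valid = (xs[1:] > xs[:-1]) & (n_left >= min_leaf) & (n_right >= min_leaf)
    weighted[~valid] = np.inf
    best = weighted.min()
    if not np.isfinite(best):
        return None
    hit_rows, hit_cols = np.nonzero(weighted <= best + _TIE_TOL)
    # first by feature order (cols is lexicographic), then by threshold
    first = np.lexsort((xs[hit_rows, hit_cols], hit_cols))[0]
    i, j = int(hit_rows[first]), int(hit_cols[first])
    threshold = 0.5 * (xs[i, j] + xs[i + 1, j])
    return int(cols[j]), float(threshold), float(weighted[i, j])


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    params: TreeTrainParams,
    n_total: int,
    root_gini: float,
    depth: int,
    rng: Optional[np.random.Generator],
    mtry: Optional[int],
    all_cols: np.ndarray,
) -> Node:
    n = X.shape[0]
    n_pos = int(y.sum())
    prob = n_pos / n
    fraction = n / n_total
    node_gini = _gini(n_pos, n)

    def leaf() -> Leaf:
        return Leaf(probability=prob, fraction=fraction)

    if node_gini == 0.0 or n < params.min_samples_split or depth >= params.max_depth:
        return leaf()

    if mtry is not None and mtry < all_cols.size:
        assert rng is not None
        cols = np.sort(rng.choice(all_cols, size=mtry, replace=False))
    else:
        cols = all_cols
    found = _best_split(X, y, cols, params.min_leaf)
    if found is None:
        return leaf()
    col, threshold, weighted = found
    # rpart-style complexity gate: impurity decrease relative to the root
    improvement = (n / n_total) * (node_gini - weighted)
    if root_gini > 0 and improvement < params.complexity_threshold * root_gini:
        return leaf()

    high_mask = X[:, col] >= threshold
    child_args = (genes, params, n_total, root_gini, depth + 1, rng, mtry, all_cols)
    low = _grow(X[~high_mask], y[~high_mask], *child_args)
    high = _grow(X[high_mask], y[high_mask], *child_args)
    return Split(
        gene=genes[col],
        threshold=threshold,
        low=low,
        high=high,
        probability=prob,
        fraction=fraction,
    )


def _percentile_frame(data: LabeledDataset) -> pd.DataFrame:
    frame = data.matrix.data
    values = frame.to_numpy()
    if values.size and (values.min() < 0 or values.max() > 100):
        raise ValueError(
            "tree induction expects rank-percentile values in [0, 100]; "
            "run rank_percentile first"
        )
    return frame


def fit_tree(
    data: LabeledDataset,
    params: TreeTrainParams = TreeTrainParams(),
    tree_id: str = "",
    _rng: Optional[np.random.Generator] = None,
    _mtry: Optional[int] = None,
) -> DecisionTree:
    """Induce a decision tree from a labeled dataset in percentile space.

    Leaf probabilities are the fraction of hypoxic training samples in the
    leaf.  A single-class dataset yields a single-leaf tree (not an error).
    ``_rng``/``_mtry`` enable per-split random feature subsampling and are
    used by the random-forest layer.
    """
    frame = _percentile_frame(data)
    if frame.shape[1] == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    if params.feature_subset is not None:
        missing = [g for g in params.feature_subset if g not in frame.index]
        if missing:
            raise KeyError(f"feature_subset gene {missing[0]!r} not in matrix")
        frame = frame.loc[list(params.feature_subset)]

    X = frame.to_numpy().T  # samples x genes
    y = (data.labels.to_numpy() == HYPOXIC)
    genes = list(frame.index)
    # columns in gene-ID lexicographic order fixes the split tie-break
    all_cols = np.array(sorted(range(len(genes)), key=genes.__getitem__), dtype=int)
    root_gini = _gini(int(y.sum()), y.size)
    root = _grow(
        X, y, genes, params, X.shape[0], root_gini, 0, _rng, _mtry, all_cols
    )
    return DecisionTree(root=root, tree_id=tree_id)


# ---------------------------------------------------------------------------
# prediction


class CompiledTree:
    """Array form of a tree for vectorized routing of many samples."""

    __slots__ = ("feature", "threshold", "low", "high", "prob", "is_leaf")

    def __init__(self, tree: DecisionTree, gene_pos: dict[str, int]):
        feature: list[int] = []
        threshold: list[float] = []
        low: list[int] = []
        high: list[int] = []
        prob: list[float] = []
        is_leaf: list[bool] = []

        def add(node: Node) -> int:
            idx = len(feature)
            feature.append(-1)
            threshold.append(np.nan)
            low.append(-1)
            high.append(-1)
            is_leaf.append(isinstance(node, Leaf))
            prob.append(node.probability)
            if isinstance(node, Split):
                if node.gene not in gene_pos:
                    raise KeyError(
                        f"gene {node.gene!r} required by tree "
                        f"{tree.tree_id!r} is absent from the matrix"
                    )
                feature[idx] = gene_pos[node.gene]
                threshold[idx] = node.threshold
                low[idx] = add(node.low)
                high[idx] = add(node.high)
            return idx

        add(tree.root)
        self.feature = np.array(feature, dtype=np.int64)
        self.threshold = np.array(threshold, dtype=float)
        self.low = np.array(low, dtype=np.int64)
        self.high = np.array(high, dtype=np.int64)
        self.prob = np.array(prob, dtype=float)
        self.is_leaf = np.array(is_leaf, dtype=bool)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hypoxia probability per row of ``X`` (samples x genes)."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            active = np.flatnonzero(~self.is_leaf[node])
            if active.size == 0:
                break
            cur = node[active]
            vals = X[active, self.feature[cur]]
            node[active] = np.where(
                vals >= self.threshold[cur], self.high[cur], self.low[cur]
            )
        return self.prob[node]


def predict_tree(tree: DecisionTree, rpm: RankPercentileMatrix) -> pd.Series:
    """Route each sample root-to-leaf; return its leaf hypoxia probability.

    Raises ``KeyError`` naming the gene and tree if a referenced gene is
    absent (filter the ensemble by available features to avoid this).
    """
    gene_pos = {g: i for i, g in enumerate(rpm.gene_ids)}
    compiled = CompiledTree(tree, gene_pos)
    probs = compiled.predict(rpm.values.T)
    return pd.Series(probs, index=rpm.data.columns, name="hypoxia_probability")


# ---------------------------------------------------------------------------
# rendering


def _node_text(node: Node) -> str:
    return f"{node.label} p={node.probability:.2f} n={node.fraction:.0%}"


def render_tree(tree: DecisionTree) -> str:
    """Human-readable indented rendering of a tree.

    Each node shows its class (N normoxic / H hypoxic), the hypoxia
    probability of the training samples in the node, and the fraction of
    the training set it holds; internal nodes additionally show the gene
    and percentile threshold tested.
    """

    def render(node: Node, indent: int, prefix: str) -> list[str]:
        pad = "  " * indent
        if isinstance(node, Leaf):
            return [f"{pad}{prefix}{_node_text(node)}"]
        head = f"{pad}{prefix}{node.gene} >= {node.threshold:g} [{_node_text(node)}]"
        lines = [head]
        lines += render(node.high, indent + 1, ">=: ")
        lines += render(node.low, indent + 1, "< : ")
        return lines

    return "\n".join(render(tree.root, 0, ""))
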