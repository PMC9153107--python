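"""Mass tree generation, accuracy filtering, and consensus classification.

The classifier-building recipe: train a large population of small decision
trees, each on an independent random 70/30 split of the labeled cohort
restricted to the selected signature genes; keep the trees whose held-out
accuracy strictly exceeds 0.95; optionally narrow to the top-k trees by
mean F1 across validation cohorts.  A sample is classified by the *mean*
of the per-tree leaf hypoxia probabilities and called hypoxic when that
mean strictly exceeds the probability threshold (default 0.5).

Datasets lacking a gene some trees require (e.g. a lncRNA absent from an
annotation) are handled at the ensemble level: drop exactly the trees that
reference unavailable genes and classify with the rest.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hyporank.cart import (
    CompiledTree,
    DecisionTree,
    Leaf,
    Split,
    TreeTrainParams,
    _gini,
    _grow,
    _percentile_frame,
    predict_tree,
)
from hyporank.ranks import RankPercentileMatrix
from hyporank.simulate import HYPOXIC, NORMOXIC, LabeledDataset

__all__ = [
    "TreeEnsemble",
    "ClassificationResult",
    "EvalReport",
    "generate_tree_population",
    "filter_by_accuracy",
    "select_top_k_by_f1",
    "filter_by_available_features",
    "ensemble_predict",
    "evaluate",
    "roc_auc",
]


@dataclass(frozen=True)
class TreeEnsemble:
    """A curated collection of decision trees with per-tree holdout metrics."""

    trees: tuple[DecisionTree, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def genes(self) -> tuple[str, ...]:
        """Sorted union of genes referenced by any member tree."""
        out: set[str] = set()
        for tree in self.trees:
            out.update(tree.genes())
        return tuple(sorted(out))

    def tree_ids(self) -> list[str]:
        return [t.tree_id for t in self.trees]


@dataclass(frozen=True)
class ClassificationResult:
    """Consensus classification of a set of samples.

    ``per_tree`` holds the leaf probability assigned by every tree (rows)
    to every sample (columns); ``mean_probability`` is their mean and the
    label is hypoxic iff it strictly exceeds ``threshold``.
    """

    per_tree: pd.DataFrame
    mean_probability: pd.Series
    labels: pd.Series
    threshold: float
    n_trees_used: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_probability": self.mean_probability,
                "label": self.labels,
                "n_trees_used": self.n_trees_used,
            }
        )


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and summary metrics (hypoxic = positive class)."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "precision_undefined": self.precision_undefined,
        }


def _f1_counts(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def generate_tree_population(
    data: LabeledDataset,
    candidate_genes: list[str],
    n_candidates: int = 10000,
    train_frac: float = 0.7,
    params: TreeTrainParams = TreeTrainParams(),
    seed: int = 0,
    features_per_tree: "int | None" = None,
) -> list[DecisionTree]:
    """Train many candidate trees, each on its own random 70/30 split.

    Every candidate draws an independent random ``train_frac`` training
    split of the cohort (resampled, with bounded retries, if a draw leaves
    a single-class training set), fits a tree on the candidate genes only,
    and is scored on its own held-out remainder.  Holdout accuracy and F1
    are stored in each tree's ``metadata``.

    ``features_per_tree`` additionally restricts every candidate tree to
    its own random subset of the candidate genes (random-subspace
    bagging).  With deterministic induction on a homogeneous cohort the
    resample alone may yield near-identical trees; subspacing restores the
    topology diversity that makes consensus ensembles — and ensembles of
    trees avoiding an unavailable gene — possible.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    frame = _percentile_frame(data)
    missing = [g for g in candidate_genes if g not in frame.index]
    if missing:
        raise KeyError(f"candidate gene {missing[0]!r} not in dataset")
    frame = frame.loc[list(candidate_genes)]
    genes = list(frame.index)
    X = np.ascontiguousarray(frame.to_numpy().T)
    y = data.labels.to_numpy() == HYPOXIC
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("train_frac leaves an empty train or holdout set")
    all_cols = np.array(sorted(range(len(genes)), key=genes.__getitem__), dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    if features_per_tree is not None and not 1 <= features_per_tree <= len(genes):
        raise ValueError("features_per_tree must lie in [1, len(candidate_genes)]")

    population: list[DecisionTree] = []
    for i in range(n_candidates):
        for _ in range(100):
            perm = rng.permutation(n)
            ytr = y[perm[:n_train]]
            if ytr.any() and not ytr.all():
                break
        else:
            raise RuntimeError("could not draw a two-class training split")
        tr, ho = perm[:n_train], perm[n_train:]
        if features_per_tree is not None and features_per_tree < len(genes):
            # subset positions of all_cols, preserving gene-ID order for
            # the documented split tie-break
            pick = rng.choice(len(all_cols), size=features_per_tree, replace=False)
            cols = all_cols[np.sort(pick)]
        else:
            cols = all_cols
        root_gini = _gini(int(ytr.sum()), ytr.size)
        root = _grow(
            X[tr], ytr, genes, params, tr.size, root_gini, 0, None, None, cols
        )
        tree = DecisionTree(root=root, tree_id=str(i + 1))
        pred = CompiledTree(tree, gene_pos).predict(X[ho]) > 0.5
        tree.metadata = {
            "holdout_accuracy": float(np.mean(pred == y[ho])),
            "holdout_f1": _f1_counts(y[ho], pred),
        }
        population.append(tree)
    return population


def _structure_key(node) -> tuple:
    if isinstance(node, Leaf):
        return ("leaf", round(node.probability, 12))
    assert isinstance(node, Split)
    return (
        node.gene,
        round(node.threshold, 12),
        _structure_key(node.low),
        _structure_key(node.high),
    )


def filter_by_accuracy(
    population: list[DecisionTree],
    min_accuracy: float = 0.95,
    deduplicate: bool = False,
) -> TreeEnsemble:
    """Keep trees with holdout accuracy strictly greater than the cutoff."""
    if not population:
        raise ValueError("tree population is empty")
    kept = [t for t in population if t.metadata.get("holdout_accuracy", 0.0) > min_accuracy]
    if deduplicate:
        seen: set[tuple] = set()
        unique = []
        for tree in kept:
            key = _structure_key(tree.root)
            if key not in seen:
                seen.add(key)
                unique.append(tree)
        kept = unique
    if not kept:
        warnings.warn(
            f"no tree exceeds accuracy {min_accuracy}; ensemble is empty",
            UserWarning,
            stacklevel=2,
        )
    return TreeEnsemble(
        trees=tuple(kept),
        provenance={"min_accuracy": min_accuracy, "population_size": len(population)},
    )


def select_top_k_by_f1(
    ensemble: TreeEnsemble,
    k: int = 20,
    validation_sets: list[LabeledDataset] = (),
) -> TreeEnsemble:
    """Retain the k trees with highest mean F1 across validation cohorts.

    Per tree, F1 is computed on each validation set (unweighted mean across
    sets); a set missing one of the tree's genes is skipped for that tree
    with a warning.  Ties break by holdout accuracy, then tree_id.
    """
    if k > len(ensemble):
        raise ValueError(f"k={k} exceeds ensemble size {len(ensemble)}")
    if not validation_sets:
        raise ValueError("at least one validation set is required")
    scored = []
    for tree in ensemble.trees:
        f1s = []
        needed = set(tree.genes())
        for vs in validation_sets:
            frame = _percentile_frame(vs)
            if not needed <= set(frame.index):
                warnings.warn(
                    f"tree {tree.tree_id!r} skipped on a validation set "
                    f"missing {sorted(needed - set(frame.index))[:3]}",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            rpm = RankPercentileMatrix(frame)
            pred = predict_tree(tree, rpm).to_numpy() > 0.5
            f1s.append(_f1_counts(vs.labels.to_numpy() == HYPOXIC, pred))
        mean_f1 = float(np.mean(f1s)) if f1s else float("-inf")
        tree.metadata["mean_validation_f1"] = mean_f1 if f1s else float("nan")
        scored.append((mean_f1, tree.metadata.get("holdout_accuracy", 0.0), tree))
    scored.sort(key=lambda item: (-item[0], -item[1], item[2].tree_id))
    top = tuple(item[2] for item in scored[:k])
    return TreeEnsemble(
        trees=top, provenance={**ensemble.provenance, "selection": f"top-{k} by mean F1"}
    )


def filter_by_available_features(
    ensemble: TreeEnsemble, available_genes: list[str]
) -> TreeEnsemble:
    """Retain exactly the trees whose genes are all available.

    This is the remedy for datasets that simply lack a signature gene (the
    canonical case being a lncRNA with no ortholog in the target species):
    classify with the trees that never consult it.
    """
    if not ensemble.trees:
        raise ValueError("ensemble is empty")
    available = set(available_genes)
    kept = tuple(t for t in ensemble.trees if set(t.genes()) <= available)
    if not kept:
        blockers = Counter()
        for tree in ensemble.trees:
            for gene in set(tree.genes()) - available:
                blockers[gene] += 1
        top = ", ".join(f"{g} (blocks {c} trees)" for g, c in blockers.most_common(5))
        raise ValueError(
            f"no tree is compatible with the available genes; "
            f"providing these genes would unblock the most trees: {top}"
        )
    return TreeEnsemble(
        trees=kept,
        provenance={**ensemble.provenance, "feature_filter": sorted(available)[:50]},
    )


def ensemble_predict(
    ensemble: TreeEnsemble,
    rpm: RankPercentileMatrix,
    threshold: float = 0.5,
) -> ClassificationResult:
    """Consensus classification: mean per-tree probability vs threshold.

    The label is hypoxic iff the mean strictly exceeds ``threshold`` — a
    mean of exactly 0.5 at the default threshold is normoxic.
    """
    if not ensemble.trees:
        raise ValueError("cannot predict with an empty ensemble")
    rows = {}
    for pos, tree in enumerate(ensemble.trees):
        key = tree.tree_id or str(pos)
        rows[f"{pos}:{key}"] = predict_tree(tree, rpm)
    per_tree = pd.DataFrame(rows).T
    per_tree.index = [k.split(":", 1)[1] for k in per_tree.index]
    mean = per_tree.mean(axis=0)
    mean.name = "mean_probability"
    labels = pd.Series(
        np.where(mean.to_numpy() > threshold, HYPOXIC, NORMOXIC),
        index=mean.index,
        name="label",
    )
    return ClassificationResult(
        per_tree=per_tree,
        mean_probability=mean,
        labels=labels,
        threshold=threshold,
        n_trees_used=len(ensemble.trees),
    )


def evaluate(labels: pd.Series, result: ClassificationResult) -> EvalReport:
    """Confusion counts and accuracy/precision/recall/F1 vs true labels."""
    truth = labels.reindex(result.labels.index)
    if truth.isna().any():
        raise ValueError("labels missing for some classified samples")
    bad = set(truth.unique()) - {NORMOXIC, HYPOXIC}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    y_true = truth.to_numpy() == HYPOXIC
    y_pred = result.labels.to_numpy() == HYPOXIC
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    total = tp + fp + fn + tn
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    denom = 2 * tp + fp + fn
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=2 * tp / denom if denom else 0.0,
        precision_undefined=precision_undefined,
    )


def roc_auc(labels: pd.Series, scores: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct score and trapezoid AUC.

    Tied scores collapse to one ROC point, so the trapezoid over a tied
    block credits exactly half a concordance per tie pair — the AUC equals
    the Mann-Whitney concordant-pair fraction.
    """
    truth = labels.reindex(scores.index)
    if truth.isna().any():
        raise ValueError("labels missing for some scored samples")
    y = truth.to_numpy() == HYPOXIC
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    s = scores.to_numpy(dtype=float)
    order = np.argsort(-s, kind="stable")
    ys, ss = y[order], s[order]
    # boundaries after each run of tied scores
    boundary = np.flatnonzero(np.diff(ss) != 0)
    boundary = np.append(boundary, ss.size - 1)
    tps = np.cumsum(ys)[boundary]
    fps = (boundary + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], ss[boundary]])
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc
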