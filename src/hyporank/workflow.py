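"""End-to-end classifier construction: rank -> select -> trees -> ensemble.

Convenience composition of the pipeline stages:

1. restrict the cohort to a candidate gene list (e.g. a meta-analysis
   derived set of hypoxia-up-regulated genes),
2. rank candidate genes by random-forest permutation importance (MDA),
3. mass-generate decision trees on the selected genes, each with its own
   random 70/30 split,
4. keep trees with holdout accuracy strictly above the cutoff, and
5. optionally narrow to the top-k trees by mean F1 on validation cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from hyporank.cart import DecisionTree, TreeTrainParams
from hyporank.ensemble import (
    TreeEnsemble,
    filter_by_accuracy,
    generate_tree_population,
    select_top_k_by_f1,
)
from hyporank.forest import ForestParams, permutation_importance, select_features
from hyporank.ranks import subset_genes
from hyporank.simulate import LabeledDataset

__all__ = ["ClassifierBuild", "build_classifier"]


@dataclass
class ClassifierBuild:
    """All artifacts of one classifier construction run."""

    importance: pd.DataFrame
    selected_genes: list[str]
    population: list[DecisionTree]
    ensemble: TreeEnsemble
    top_ensemble: TreeEnsemble
    provenance: dict = field(default_factory=dict)


def build_classifier(
    train: LabeledDataset,
    candidate_genes: Sequence[str],
    validation_sets: Sequence[LabeledDataset] = (),
    *,
    forest_params: ForestParams = ForestParams(),
    mda_iterations: int = 1000,
    mda_threshold: float = 4.0,
    mda_top_k: Optional[int] = None,
    n_candidates: int = 10000,
    train_frac: float = 0.7,
    features_per_tree: Optional[int] = None,
    tree_params: TreeTrainParams = TreeTrainParams(),
    min_accuracy: float = 0.95,
    top_k: int = 20,
    seed: int = 0,
) -> ClassifierBuild:
    """Run the full selection + tree-generation pipeline on a labeled cohort.

    ``train`` and ``validation_sets`` must be in percentile space (use
    ``LabeledDataset.to_percentiles()``).  ``top_k`` is capped at the size
    of the accuracy-filtered ensemble; with no validation sets the filtered
    ensemble itself is returned as ``top_ensemble``.
    """
    train = train.to_percentiles()
    validation_sets = [v.to_percentiles() for v in validation_sets]
    cand_rpm, missing = subset_genes(train.matrix, list(candidate_genes), on_missing="error")
    cand_data = LabeledDataset(matrix=cand_rpm, labels=train.labels)

    importance = permutation_importance(
        cand_data, forest_params, n_iterations=mda_iterations
    )
    selected = select_features(importance, mda_threshold=mda_threshold, top_k=mda_top_k)
    if not selected:
        raise ValueError("feature selection returned no genes")

    population = generate_tree_population(
        train, selected, n_candidates=n_candidates,
        train_frac=train_frac, params=tree_params, seed=seed,
        features_per_tree=features_per_tree,
    )
    ensemble = filter_by_accuracy(population, min_accuracy=min_accuracy)
    if validation_sets and len(ensemble) > 0:
        top = select_top_k_by_f1(ensemble, min(top_k, len(ensemble)), list(validation_sets))
    else:
        top = ensemble
    return ClassifierBuild(
        importance=importance,
        selected_genes=selected,
        population=population,
        ensemble=ensemble,
        top_ensemble=top,
        provenance={
            "mda_iterations": mda_iterations,
            "n_candidates": n_candidates,
            "min_accuracy": min_accuracy,
            "top_k": top_k,
            "seed": seed,
        },
    )
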