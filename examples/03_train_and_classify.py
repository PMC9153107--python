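"""Mass tree generation, accuracy filtering and consensus classification.

Simulates a labeled training cohort, trains hundreds of small decision
trees (each on its own random 70/30 split), keeps those with held-out
accuracy > 0.95, narrows to the top trees by mean F1 on a validation
cohort, and classifies an independently drawn test cohort by the mean of
the per-tree hypoxia probabilities.  Also renders one tree: each node
shows class (N/H), hypoxia probability and training-sample fraction.
"""

from dataclasses import replace

from hyporank import (
    SyntheticConfig,
    ensemble_predict,
    evaluate,
    filter_by_accuracy,
    generate_cohort,
    generate_tree_population,
    render_tree,
    roc_auc,
    select_top_k_by_f1,
)

config = SyntheticConfig(
    n_genes=500, n_samples_per_class=50, de_genes=15, effect=30.0, seed=3
)
train = generate_cohort(config).to_percentiles()
validation = generate_cohort(
    replace(config, seed=4, n_samples_per_class=25, structure_seed=3)
).to_percentiles()
test = generate_cohort(
    replace(config, seed=5, n_samples_per_class=30, structure_seed=3)
).to_percentiles()

population = generate_tree_population(
    train, list(train.truth), n_candidates=300, seed=6, features_per_tree=9
)
ensemble = filter_by_accuracy(population, min_accuracy=0.95)
top = select_top_k_by_f1(ensemble, min(20, len(ensemble)), [validation])
print(f"{len(ensemble)} of {len(population)} trees kept (holdout accuracy > 0.95),")
print(f"narrowed to top {len(top)} by mean validation F1.\n")

print("best tree (gene, percentile threshold; >= goes to the high branch):")
print(render_tree(top.trees[0]))

result = ensemble_predict(top, test.matrix, threshold=0.5)
report = evaluate(test.labels, result)
_, auc = roc_auc(test.labels, result.mean_probability)
print(f"\nindependent test cohort ({len(test.sample_ids)} samples):")
print(f"accuracy={report.accuracy:.3f} precision={report.precision:.3f} "
      f"recall={report.recall:.3f} F1={report.f1:.3f} AUC={auc:.3f}")
print("a sample is called hypoxic when the ensemble's mean probability")
print("strictly exceeds 0.5; sweep the threshold to trade recall for precision.")
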