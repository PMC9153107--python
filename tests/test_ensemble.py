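import numpy as np
import pandas as pd
import pytest

from hyporank.cart import DecisionTree, Leaf, Split, TreeTrainParams
from hyporank.ensemble import (
    ClassificationResult,
    TreeEnsemble,
    ensemble_predict,
    evaluate,
    filter_by_accuracy,
    filter_by_available_features,
    generate_tree_population,
    roc_auc,
    select_top_k_by_f1,
)
from hyporank.ranks import RankPercentileMatrix

from conftest import percentile_dataset
from oracles import auc_pair_counting

PERMISSIVE = TreeTrainParams(min_samples_split=2, min_leaf=1, max_depth=4, complexity_threshold=0.0)


def leaf_tree(prob, tree_id="", acc=1.0):
    return DecisionTree(
        root=Leaf(probability=prob, fraction=1.0),
        tree_id=tree_id,
        metadata={"holdout_accuracy": acc, "holdout_f1": acc},
    )


def stump(gene, threshold, tree_id="", acc=1.0, f1=1.0):
    return DecisionTree(
        root=Split(gene=gene, threshold=threshold,
                   low=Leaf(0.0, 0.5), high=Leaf(1.0, 0.5)),
        tree_id=tree_id,
        metadata={"holdout_accuracy": acc, "holdout_f1": f1},
    )


def separable_data(n=40, seed=0, n_noise=3, margin=0.0):
    """gA determines the label; ``margin`` keeps values away from 50."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 100, n)
    a = np.where(a > 50, 50 + margin + (a - 50) * (50 - margin) / 50,
                 (50 - margin) * a / 50)
    noise = rng.uniform(0, 100, (n_noise, n))
    labels = ["hypoxic" if v > 50 else "normoxic" for v in a]
    return percentile_dataset(np.vstack([a, noise]), labels,
                              genes=["gA"] + [f"gn{i}" for i in range(n_noise)])


class TestGenerateTreePopulation:
    def test_zero_candidates_gives_empty_list(self):
        assert generate_tree_population(separable_data(), ["gA"], n_candidates=0) == []

    def test_perfectly_separable_cohort_all_trees_perfect(self):
        data = separable_data(n=40, seed=1, margin=15.0)
        pop = generate_tree_population(
            data, ["gA"], n_candidates=20, params=PERMISSIVE, seed=2
        )
        assert len(pop) == 20
        assert all(t.metadata["holdout_accuracy"] == 1.0 for t in pop)

    def test_unknown_candidate_gene_rejected(self):
        with pytest.raises(KeyError, match="gZ"):
            generate_tree_population(separable_data(), ["gZ"], n_candidates=1)

    def test_feature_subspacing_diversifies_trees(self):
        data = separable_data(n=40, seed=7, n_noise=3, margin=10.0)
        pop = generate_tree_population(
            data, ["gA", "gn0", "gn1", "gn2"], n_candidates=30,
            params=PERMISSIVE, seed=1, features_per_tree=1,
        )
        used = {g for t in pop for g in t.genes()}
        assert len(used) > 1  # not every tree saw the dominant gene

    def test_invalid_features_per_tree_rejected(self):
        with pytest.raises(ValueError, match="features_per_tree"):
            generate_tree_population(
                separable_data(), ["gA"], n_candidates=1, features_per_tree=5
            )

    def test_reproducible_given_seed(self):
        data = separable_data(n=30, seed=3)
        kw = dict(n_candidates=10, params=PERMISSIVE, seed=5)
        a = generate_tree_population(data, ["gA", "gn0"], **kw)
        b = generate_tree_population(data, ["gA", "gn0"], **kw)
        from hyporank.cart import render_tree
        assert [render_tree(t) for t in a] == [render_tree(t) for t in b]


class TestFilterByAccuracy:
    def test_strictly_greater_cutoff(self):
        pop = [leaf_tree(1.0, "1", 0.96), leaf_tree(1.0, "2", 0.95), leaf_tree(1.0, "3", 0.80)]
        ens = filter_by_accuracy(pop, 0.95)
        assert ens.tree_ids() == ["1"]

    def test_zero_cutoff_keeps_all(self):
        pop = [leaf_tree(1.0, "1", 0.5), leaf_tree(0.0, "2", 0.1)]
        assert len(filter_by_accuracy(pop, 0.0)) == 2

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            ens = filter_by_accuracy([leaf_tree(1.0, "1", 0.5)], 0.99)
        assert len(ens) == 0

    def test_deduplication_removes_structural_twins(self):
        pop = [stump("gA", 50.0, "1"), stump("gA", 50.0, "2"), stump("gB", 30.0, "3")]
        assert len(filter_by_accuracy(pop, 0.0, deduplicate=True)) == 2


class TestSelectTopKByF1:
    def test_k_equal_to_size_is_identity(self):
        ens = TreeEnsemble(trees=(stump("gA", 50.0, "1"), stump("gA", 60.0, "2")))
        top = select_top_k_by_f1(ens, 2, [separable_data(seed=4)])
        assert set(top.tree_ids()) == {"1", "2"}

    def test_perfect_tree_ranked_above_useless_tree(self):
        data = separable_data(seed=5)
        ens = TreeEnsemble(trees=(leaf_tree(0.0, "useless"), stump("gA", 50.0, "perfect")))
        top = select_top_k_by_f1(ens, 1, [data])
        assert top.tree_ids() == ["perfect"]

    def test_mean_f1_ordering_matches_hand_computation(self):
        # two tiny fixtures, three stumps with hand-computable F1
        d1 = percentile_dataset(
            [[80.0, 60.0, 40.0, 20.0]], ["hypoxic", "hypoxic", "normoxic", "normoxic"],
            genes=["gA"],
        )
        d2 = percentile_dataset(
            [[80.0, 30.0, 70.0, 20.0]], ["hypoxic", "normoxic", "hypoxic", "normoxic"],
            genes=["gA"],
        )
        t_50 = stump("gA", 50.0, "t50")   # d1: F1=1.0; d2: F1=1.0 -> mean 1.0
        t_70 = stump("gA", 65.0, "t65")   # d1: tp1 fn1 -> F1=2/3; d2: F1 = 2*2/(4+0+0)? hand: preds 80,70 -> tp2 fp0 fn0 = 1.0 -> mean 5/6
        t_90 = stump("gA", 90.0, "t90")   # no positives: F1=0 both -> 0
        ens = TreeEnsemble(trees=(t_90, t_70, t_50))
        top = select_top_k_by_f1(ens, 3, [d1, d2])
        assert top.tree_ids() == ["t50", "t65", "t90"]
        f1s = [t.metadata["mean_validation_f1"] for t in top.trees]
        np.testing.assert_allclose(f1s, [1.0, (2 / 3 + 1.0) / 2, 0.0])

    def test_validation_set_missing_gene_skipped_with_warning(self):
        d_ok = separable_data(seed=6)
        d_missing = percentile_dataset(
            [[80.0, 20.0]], ["hypoxic", "normoxic"], genes=["gOther"]
        )
        ens = TreeEnsemble(trees=(stump("gA", 50.0, "1"),))
        with pytest.warns(UserWarning, match="missing"):
            top = select_top_k_by_f1(ens, 1, [d_ok, d_missing])
        assert top.trees[0].metadata["mean_validation_f1"] == 1.0


class TestFilterByAvailableFeatures:
    def test_removes_exactly_dependent_trees(self):
        ens = TreeEnsemble(trees=(stump("gX", 50.0, "usesX"), stump("gA", 50.0, "usesA")))
        kept = filter_by_available_features(ens, ["gA", "gB"])
        assert kept.tree_ids() == ["usesA"]

    def test_all_genes_available_is_identity(self):
        ens = TreeEnsemble(trees=(stump("gX", 50.0, "1"), stump("gA", 50.0, "2")))
        assert filter_by_available_features(ens, ["gA", "gX"]).tree_ids() == ["1", "2"]

    def test_empty_result_error_names_blocking_genes(self):
        ens = TreeEnsemble(trees=(stump("gX", 50.0, "1"),))
        with pytest.raises(ValueError, match="gX"):
            filter_by_available_features(ens, ["gA"])


class TestEnsemblePredict:
    def rpm(self, value=60.0):
        return RankPercentileMatrix(
            pd.DataFrame([[value]], index=["gA"], columns=["s0"])
        )

    def test_mean_of_tree_probabilities(self):
        ens = TreeEnsemble(trees=(leaf_tree(0.9), leaf_tree(0.8), leaf_tree(0.1)))
        res = ensemble_predict(ens, self.rpm())
        assert np.isclose(res.mean_probability["s0"], 0.6)
        assert res.labels["s0"] == "hypoxic"
        assert res.n_trees_used == 3

    def test_mean_exactly_half_is_normoxic(self):
        ens = TreeEnsemble(trees=(leaf_tree(1.0), leaf_tree(0.0)))
        res = ensemble_predict(ens, self.rpm())
        assert np.isclose(res.mean_probability["s0"], 0.5)
        assert res.labels["s0"] == "normoxic"

    def test_stricter_threshold_flips_call(self):
        ens = TreeEnsemble(trees=(leaf_tree(0.9), leaf_tree(0.8), leaf_tree(0.1)))
        res = ensemble_predict(ens, self.rpm(), threshold=0.7)
        assert res.labels["s0"] == "normoxic"

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_predict(TreeEnsemble(trees=()), self.rpm())

    def test_consensus_bounded_by_per_tree_extremes(self):
        rng = np.random.default_rng(8)
        trees = tuple(stump("gA", t, str(i)) for i, t in enumerate(rng.uniform(10, 90, 7)))
        rpm = RankPercentileMatrix(
            pd.DataFrame([rng.uniform(0, 100, 9)], index=["gA"])
        )
        res = ensemble_predict(TreeEnsemble(trees=trees), rpm)
        assert (res.per_tree.min(axis=0) <= res.mean_probability + 1e-12).all()
        assert (res.mean_probability <= res.per_tree.max(axis=0) + 1e-12).all()

    def test_identical_trees_equal_single_tree(self):
        rpm = RankPercentileMatrix(
            pd.DataFrame([[20.0, 70.0]], index=["gA"], columns=["s0", "s1"])
        )
        single = ensemble_predict(TreeEnsemble(trees=(stump("gA", 50.0, "1"),)), rpm)
        triple = ensemble_predict(
            TreeEnsemble(trees=tuple(stump("gA", 50.0, str(i)) for i in range(3))), rpm
        )
        assert (single.mean_probability == triple.mean_probability).all()

    def test_hypoxic_calls_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        trees = tuple(stump("gA", t, str(i)) for i, t in enumerate(rng.uniform(5, 95, 11)))
        rpm = RankPercentileMatrix(
            pd.DataFrame([rng.uniform(0, 100, 30)], index=["gA"])
        )
        ens = TreeEnsemble(trees=trees)
        counts = [
            int((ensemble_predict(ens, rpm, threshold=t).labels == "hypoxic").sum())
            for t in np.linspace(0.0, 1.0, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEvaluate:
    def result_from(self, labels):
        idx = [f"s{i}" for i in range(len(labels))]
        lab = pd.Series(labels, index=idx)
        return ClassificationResult(
            per_tree=pd.DataFrame(),
            mean_probability=pd.Series(
                [1.0 if v == "hypoxic" else 0.0 for v in labels], index=idx
            ),
            labels=lab,
            threshold=0.5,
            n_trees_used=1,
        )

    def test_closed_form_confusion_example(self):
        # TP=3 FP=1 FN=1 TN=5
        truth = ["hypoxic"] * 4 + ["normoxic"] * 6
        pred = ["hypoxic"] * 3 + ["normoxic"] + ["hypoxic"] + ["normoxic"] * 5
        rep = evaluate(pd.Series(truth, index=[f"s{i}" for i in range(10)]), self.result_from(pred))
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 5)
        assert np.isclose(rep.accuracy, 0.8)
        assert np.isclose(rep.precision, 0.75)
        assert np.isclose(rep.recall, 0.75)
        assert np.isclose(rep.f1, 0.75)

    def test_perfect_prediction_all_ones(self):
        truth = ["hypoxic", "normoxic", "hypoxic"]
        rep = evaluate(pd.Series(truth, index=["s0", "s1", "s2"]), self.result_from(truth))
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_all_normoxic_prediction_flags_undefined_precision(self):
        truth = ["hypoxic"] * 5 + ["normoxic"] * 5
        rep = evaluate(
            pd.Series(truth, index=[f"s{i}" for i in range(10)]),
            self.result_from(["normoxic"] * 10),
        )
        assert rep.accuracy == 0.5 and rep.f1 == 0.0
        assert rep.precision == 0.0 and rep.precision_undefined

    def test_unknown_label_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="unknown labels"):
            evaluate(
                pd.Series(["anoxic", "normoxic"], index=["s0", "s1"]),
                self.result_from(["hypoxic", "normoxic"]),
            )


class TestRocAuc:
    def series(self, labels, scores):
        idx = [f"s{i}" for i in range(len(labels))]
        return pd.Series(labels, index=idx), pd.Series(scores, index=idx)

    def test_perfect_separation_auc_one(self):
        labels, scores = self.series(
            ["hypoxic", "hypoxic", "normoxic", "normoxic"], [0.9, 0.8, 0.4, 0.2]
        )
        points, auc = roc_auc(labels, scores)
        assert auc == 1.0
        assert (points.iloc[0][["fpr", "tpr"]] == 0.0).all()
        assert (points.iloc[-1][["fpr", "tpr"]] == 1.0).all()

    def test_reversed_scores_auc_zero(self):
        labels, scores = self.series(
            ["hypoxic", "hypoxic", "normoxic", "normoxic"], [0.2, 0.4, 0.8, 0.9]
        )
        assert roc_auc(labels, scores)[1] == 0.0

    def test_single_class_rejected(self):
        labels, scores = self.series(["hypoxic", "hypoxic"], [0.2, 0.4])
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(labels, scores)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = 40
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            scores = rng.integers(0, 6, n) / 5.0  # heavy ties
            labels = pd.Series(
                ["hypoxic" if v else "normoxic" for v in y],
                index=[f"s{i}" for i in range(n)],
            )
            s = pd.Series(scores, index=labels.index)
            _, auc = roc_auc(labels, s)
            assert np.isclose(auc, auc_pair_counting(y, scores))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.random(60) < 0.4
        y[:2] = [True, False]
        scores = np.round(rng.random(60), 2)
        labels = pd.Series(
            ["hypoxic" if v else "normoxic" for v in y],
            index=[f"s{i}" for i in range(60)],
        )
        _, auc = roc_auc(labels, pd.Series(scores, index=labels.index))
        assert np.isclose(auc, roc_auc_score(y, scores))
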