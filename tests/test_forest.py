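"""Behaviour of the random-subspace forest ensembles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestscan.forest import (
    ForestConfig,
    misclassification_report,
    run_ensemble,
    stratified_split,
    subset_scan,
    train_model,
)
from forestscan.matrix import GenotypeMatrix, LabelSet, impute_for_model
from forestscan.sim import simulate_genotypes
from tests.test_sim import _spec


def _toy_matrix(values, labels):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    variants = pd.DataFrame(
        {
            "scaffold": ["sc1"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    ids = [f"s{i}" for i in range(n)]
    return (
        GenotypeMatrix(values, ids, variants),
        LabelSet(pd.Series(labels, index=ids)),
    )


class TestStratifiedSplit:
    def test_exact_divisibility(self):
        labels = LabelSet(
            pd.Series(["A"] * 100 + ["B"] * 100, index=[f"s{i}" for i in range(200)])
        )
        train, test = stratified_split(labels, 0.75, seed=0)
        tr = labels.labels[train]
        assert (tr == "A").sum() == 75 and (tr == "B").sum() == 75
        assert sorted(train + test) == sorted(labels.labels.index)
        assert not set(train) & set(test)

    def test_rounding_within_one_sample(self):
        labels = LabelSet(
            pd.Series(["A"] * 10 + ["B"] * 200, index=[f"s{i}" for i in range(210)])
        )
        train, _ = stratified_split(labels, 0.75, seed=3)
        n_a = (labels.labels[train] == "A").sum()
        assert n_a in (7, 8)

    def test_deterministic_per_seed(self):
        labels = LabelSet(
            pd.Series(["A"] * 20 + ["B"] * 20, index=[f"s{i}" for i in range(40)])
        )
        assert stratified_split(labels, 0.75, 5) == stratified_split(labels, 0.75, 5)
        assert stratified_split(labels, 0.75, 5) != stratified_split(labels, 0.75, 6)

    def test_singleton_class_named_in_error(self):
        labels = LabelSet(pd.Series({"x": "rare", "a": "B", "b": "B"}))
        with pytest.raises(ValueError, match="rare"):
            stratified_split(labels, 0.75, 0)


class TestTrainModel:
    def test_perfect_separator_full_features(self):
        """One perfectly separating variant: accuracy 1, top importance."""
        values = np.zeros((8, 3), dtype=np.int8)
        labels = ["A"] * 4 + ["B"] * 4
        values[4:, 1] = 2  # variant 1 separates the classes
        values[:, 2] = [0, 1, 2, 0, 1, 2, 0, 1]  # noise
        matrix, label_set = _toy_matrix(values, labels)
        config = ForestConfig(n_models=1, n_trees=25, feature_fraction=1.0, base_seed=0)
        split = stratified_split(label_set, 0.5, seed=1)
        res = train_model(matrix, label_set, split, config, model_seed=2)
        assert res.test_accuracy == 1.0
        assert res.importance.argmax() == 1
        assert res.importance.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_tree_importance_matches_hand_gini(self):
        """1 tree, 2 variants: importance equals the hand-computed split gain.

        The bootstrap draw is replicated with the same seeded generator,
        and the normalized Gini decrease of the only possible split is
        computed by hand from the bootstrap class counts.
        """
        values = np.array([[0, 1], [0, 1], [2, 1], [2, 1]], dtype=np.int8)
        matrix, label_set = _toy_matrix(values, ["A", "A", "B", "B"])
        seed = 9
        config = ForestConfig(n_models=1, n_trees=1, feature_fraction=1.0, base_seed=0)
        res = train_model(
            matrix, label_set, (["s0", "s1", "s2", "s3"], ["s0", "s3"]), config, model_seed=seed
        )
        # replicate the generator's draws: feature subset then bootstrap
        rng = np.random.default_rng(seed)
        rng.choice(2, size=2, replace=False)
        boot = rng.integers(0, 4, size=4)
        y_boot = np.array([0, 0, 1, 1])[boot]
        n1 = y_boot.sum()
        gini_parent = 1 - (n1 / 4) ** 2 - (1 - n1 / 4) ** 2
        if 0 < n1 < 4:
            # variant 0 splits to two pure leaves: gain = parent impurity;
            # normalized importance puts all mass on it
            assert gini_parent > 0
            np.testing.assert_allclose(res.importance, [1.0, 0.0], atol=1e-12)
        else:  # degenerate bootstrap: no split possible
            np.testing.assert_allclose(res.importance, [0.0, 0.0])

    def test_null_labels_accuracy_in_binomial_band(self):
        """With permuted labels, accuracy stays in the 99% binomial band."""
        rng = np.random.default_rng(0)
        values = rng.integers(0, 3, size=(40, 60)).astype(np.int8)
        labels = list(rng.permutation(["A"] * 20 + ["B"] * 20))
        matrix, label_set = _toy_matrix(values, labels)
        config = ForestConfig(n_models=20, n_trees=15, feature_fraction=0.3, base_seed=7)
        ens = run_ensemble(matrix, label_set, config)
        n_test_total = sum(len(m.test_sample_ids) for m in ens.models)
        correct = round(ens.mean_accuracy * n_test_total)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_test_total, 0.5)
        assert lo <= correct <= hi


class TestEnsemble:
    def test_dedup_is_per_variant_max(self, small_ensemble):
        config, ens = small_ensemble
        stacked = np.vstack([m.importance for m in ens.models])
        np.testing.assert_allclose(ens.dedup_importance, stacked.max(axis=0))
        assert ens.mean_accuracy == pytest.approx(np.mean(ens.accuracies))

    def test_model_importances_normalized(self, small_ensemble):
        _, ens = small_ensemble
        for m in ens.models:
            assert (m.importance >= 0).all()
            assert m.importance.sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_seeds_zero_variance(self, planted):
        _, matrix, labels, _ = planted
        full = impute_for_model(matrix)
        config = ForestConfig(n_models=2, n_trees=10, feature_fraction=0.1, base_seed=3)
        a = run_ensemble(full, labels, config)
        b = run_ensemble(full, labels, config)
        assert a.accuracies == b.accuracies
        np.testing.assert_array_equal(a.dedup_importance, b.dedup_importance)

    def test_tally_bounded_by_membership(self, small_ensemble):
        config, ens = small_ensemble
        for s, count in ens.misclassification_tally.items():
            assert 0 <= count <= ens.test_membership[s] <= config.n_models

    def test_accuracy_monotone_in_frequency_gap(self):
        """Larger planted frequency gaps never reduce mean accuracy."""
        accs = []
        for pair in [(0.45, 0.45), (0.3, 0.6), (0.05, 0.95)]:
            matrix, labels, _ = simulate_genotypes(
                _spec(causal_freq_pair=pair, n_variants=300, seed=21)
            )
            config = ForestConfig(n_models=3, n_trees=40, feature_fraction=0.2, base_seed=2)
            accs.append(run_ensemble(impute_for_model(matrix), labels, config).mean_accuracy)
        assert accs[0] <= accs[1] <= accs[2]


class TestReportsAndSubsets:
    def test_separable_data_empty_report(self):
        values = np.zeros((12, 2), dtype=np.int8)
        values[6:, 0] = 2
        matrix, label_set = _toy_matrix(values, ["A"] * 6 + ["B"] * 6)
        config = ForestConfig(n_models=3, n_trees=20, feature_fraction=1.0, base_seed=0)
        ens = run_ensemble(matrix, label_set, config)
        report = misclassification_report(ens, label_set)
        assert report.empty

    def test_planted_label_flip_tops_report(self):
        values = np.zeros((20, 3), dtype=np.int8)
        values[10:, 0] = 2
        labels = ["A"] * 10 + ["B"] * 10
        labels[3] = "B"  # mislabelled sample s3 (genotype says A)
        matrix, label_set = _toy_matrix(values, labels)
        config = ForestConfig(n_models=6, n_trees=20, feature_fraction=1.0, base_seed=1)
        ens = run_ensemble(matrix, label_set, config)
        report = misclassification_report(ens, label_set)
        assert not report.empty
        assert report.iloc[0]["sample"] == "s3"
        assert report.iloc[0]["majority_predicted"] == "A"
        assert (report["n_models_misclassified"] <= config.n_models).all()

    def test_subset_scan_equals_ensemble_on_subset(self, planted, small_ensemble):
        """A region spanning a whole scaffold reproduces run_ensemble on it."""
        spec, matrix, labels, _ = planted
        config, _ = small_ensemble
        full = impute_for_model(matrix)
        sub = subset_scan(full, labels, ("sc1", 0, 500_000), config)
        direct = run_ensemble(full.subset_region("sc1", 0, 500_000), labels, config)
        assert sub.accuracies == direct.accuracies
        np.testing.assert_array_equal(sub.dedup_importance, direct.dedup_importance)

    def test_empty_region_errors(self, planted):
        _, matrix, labels, _ = planted
        with pytest.raises(ValueError):
            subset_scan(impute_for_model(matrix), labels, ("sc1", 0, 1), ForestConfig())
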