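"""Ensembles of independently split random-forest classifiers.

The scan trains ``n_models`` random forests, each on its own stratified
75/25 train/test split of the samples. Within a forest, every decision
tree sees a bootstrap resample of the training samples and its *own*
uniform random subset of ``feature_fraction`` of the variant columns (a
random-subspace draw made once per tree, not per split) — with tens of
thousands of tightly linked variants this keeps any single LD block from
dominating every tree. Per-variant importance is the mean over trees of
the normalized impurity (Gini) decrease, with variants outside a tree's
subset contributing zero for that tree; across models the per-variant
maximum ("deduplicated importance") is kept.

Model quality is summarised by per-model test accuracy and by a tally of
how many models misclassified each sample — samples misclassified by many
independent splits are candidate label problems or genuine genetic
outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .matrix import MISSING, GenotypeMatrix, LabelSet

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    """Configuration of the forest ensemble.

    Defaults: 42 models, 75% training fraction, 5000 trees per model and
    a 5% per-tree variant subset.
    """

    n_models: int = 42
    train_fraction: float = 0.75
    n_trees: int = 5000
    feature_fraction: float = 0.05
    base_seed: int = 0
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")

    def n_subset_features(self, n_variants: int) -> int:
        m = int(np.ceil(self.feature_fraction * n_variants))
        if m < 1:
            raise ValueError("feature subset is empty; raise feature_fraction")
        return m


@dataclass
class ModelResult:
    """One trained forest: its split, accuracy and importance vector."""

    model_index: int
    test_sample_ids: list[str]
    test_accuracy: float
    misclassified_sample_ids: list[str]
    predicted_labels: dict[str, str]  # test sample -> predicted class label
    importance: np.ndarray = field(repr=False)


@dataclass
class EnsembleResult:
    """Aggregate over all models of an ensemble run."""

    models: list[ModelResult]
    class_labels: list[str]
    sample_ids: list[str]
    mean_accuracy: float
    misclassification_tally: dict[str, int]
    test_membership: dict[str, int]  # sample -> number of models with it in the test set
    dedup_importance: np.ndarray = field(repr=False)

    @property
    def accuracies(self) -> list[float]:
        return [m.test_accuracy for m in self.models]


def stratified_split(
    labels: LabelSet, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Partition samples into train/test, stratified by class.

    Each class contributes a train share within one sample of
    ``train_fraction`` (round-half-up), with both sides kept non-empty.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in labels.classes:
        ids = labels.labels.index[labels.labels == cls].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot stratify")
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return train, test


def _check_matrix(matrix: GenotypeMatrix) -> None:
    if matrix.has_missing:
        raise ValueError("matrix contains MISSING entries; run impute_for_model first")


def train_model(
    matrix: GenotypeMatrix,
    labels: LabelSet,
    split: tuple[list[str], list[str]],
    config: ForestConfig,
    model_seed: int,
    model_index: int = 0,
) -> ModelResult:
    """Train one random-subspace forest on a given split and score it.

    Majority vote over trees; exact vote ties resolve to the lowest class
    label.
    """
    _check_matrix(matrix)
    train_ids, test_ids = split
    classes = labels.classes
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    tr = np.array([idx[s] for s in train_ids])
    te = np.array([idx[s] for s in test_ids])
    y = labels.for_samples(matrix.sample_ids)
    X = matrix.values
    n_variants = matrix.n_variants
    m = config.n_subset_features(n_variants)

    rng = np.random.default_rng(model_seed)
    importance = np.zeros(n_variants)
    votes = np.zeros((len(te), len(classes)), dtype=np.int32)
    Xtr, ytr = X[tr], y[tr]
    Xte = X[te]
    sample_weight = None
    if config.class_weight == "balanced":
        counts = np.bincount(ytr, minlength=len(classes)).astype(float)
        sample_weight = (len(ytr) / (len(classes) * counts))[ytr]
    n_splitting_trees = 0
    for _ in range(config.n_trees):
        feat = rng.choice(n_variants, size=m, replace=False)
        boot = rng.integers(0, len(tr), size=len(tr))
        tree = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(0, 2**31 - 1))
        )
        sw = sample_weight[boot] if sample_weight is not None else None
        tree.fit(Xtr[boot][:, feat], ytr[boot], sample_weight=sw)
        if tree.tree_.node_count > 1:
            importance[feat] += tree.feature_importances_
            n_splitting_trees += 1
        pred = tree.predict(Xte[:, feat]).astype(int)
        votes[np.arange(len(te)), pred] += 1
    if n_splitting_trees:
        importance /= n_splitting_trees
    pred_class = votes.argmax(axis=1)  # argmax takes the lowest label on ties
    correct = pred_class == y[te]
    mis = [test_ids[i] for i in np.nonzero(~correct)[0]]
    predicted = {test_ids[i]: classes[pred_class[i]] for i in range(len(te))}
    return ModelResult(
        model_index=model_index,
        test_sample_ids=list(test_ids),
        test_accuracy=float(correct.mean()) if len(te) else float("nan"),
        misclassified_sample_ids=mis,
        predicted_labels=predicted,
        importance=importance,
    )


def run_ensemble(
    matrix: GenotypeMatrix, labels: LabelSet, config: ForestConfig
) -> EnsembleResult:
    """Train ``n_models`` forests on independent splits and aggregate.

    Model ``i`` uses seed ``base_seed + i`` for both its split and its
    trees. Aggregates the mean accuracy, the per-sample misclassification
    tally and the per-variant maximum importance across models.
    """
    _check_matrix(matrix)
    models: list[ModelResult] = []
    tally: dict[str, int] = {s: 0 for s in matrix.sample_ids}
    membership: dict[str, int] = {s: 0 for s in matrix.sample_ids}
    dedup = np.zeros(matrix.n_variants)
    for i in range(config.n_models):
        seed = config.base_seed + i
        split = stratified_split(labels, config.train_fraction, seed)
        res = train_model(matrix, labels, split, config, model_seed=seed, model_index=i)
        models.append(res)
        for s in res.test_sample_ids:
            membership[s] += 1
        for s in res.misclassified_sample_ids:
            tally[s] += 1
        np.maximum(dedup, res.importance, out=dedup)
    min_membership = min(membership.values()) if membership else 0
    logger.info(
        "ensemble of %d models: mean accuracy %.4f, min test-set membership %d",
        config.n_models,
        float(np.mean([m.test_accuracy for m in models])),
        min_membership,
    )
    return EnsembleResult(
        models=models,
        class_labels=labels.classes,
        sample_ids=list(matrix.sample_ids),
        mean_accuracy=float(np.mean([m.test_accuracy for m in models])),
        misclassification_tally=tally,
        test_membership=membership,
        dedup_importance=dedup,
    )


def misclassification_report(ensemble: EnsembleResult, labels: LabelSet) -> pd.DataFrame:
    """Per-sample misclassification table, most-often-misclassified first.

    Columns: ``n_models_misclassified, sample, true_label,
    majority_predicted`` — one row per sample misclassified at least once.
    ``majority_predicted`` is the most frequent wrong-or-right prediction
    over the models whose test set contained the sample.
    """
    rows = []
    for sample, count in ensemble.misclassification_tally.items():
        if count == 0:
            continue
        preds = [
            m.predicted_labels[sample]
            for m in ensemble.models
            if sample in m.predicted_labels
        ]
        majority = pd.Series(preds).mode().iloc[0] if preds else ""
        rows.append((count, sample, labels.labels[sample], majority))
    df = pd.DataFrame(
        rows, columns=["n_models_misclassified", "sample", "true_label", "majority_predicted"]
    )
    return df.sort_values(
        ["n_models_misclassified", "sample"], ascending=[False, True]
    ).reset_index(drop=True)


def subset_scan(
    matrix: GenotypeMatrix,
    labels: LabelSet,
    region: tuple[str, int, int],
    config: ForestConfig,
) -> EnsembleResult:
    """Run the ensemble on the variants inside one genomic region only.

    ``region`` is (scaffold, start, end) in 0-based half-open bp. Used to
    ask how well a single locus separates the groups.
    """
    sub = matrix.subset_region(*region)
    return run_ensemble(sub, labels, config)
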