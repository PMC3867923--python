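"""Comparison classifiers: Citation-kNN, whole-image SVM, and a
bag-dissolution (WEMISVM-style) SVM.

* **Citation-kNN** votes over *references* (the R training bags nearest to
  the test bag under the minimum Hausdorff bag distance) and *citers*
  (training bags that count the test bag among their C_cite nearest
  neighbours).  The minimum Hausdorff distance between two bags is the
  smallest Euclidean distance between any pair of their instance feature
  vectors; it is symmetric and zero for identical bags but violates the
  triangle inequality, so it is a dissimilarity, not a metric.
* **Whole-image SVM** ignores the bag structure entirely: one GLCM feature
  vector per full preprocessed frame, classified by a tuned RBF-SVM.
* **WEMISVM-style** dissolves every bag (instances inherit the bag label),
  trains one instance-level SVM, and labels a test bag with the sign of the
  mean instance decision value (a single-model variant of the original
  ensemble formulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .bags import Bag
from .errors import ConfigurationError, ParameterError, PredictionError
from .svm_tuning import LOConfig, PSOConfig, TrainedClassifier, train_svm, tune_svm_params
from .texture import GLCMConfig, instance_features

__all__ = [
    "CitationConfig",
    "min_hausdorff_distance",
    "citation_knn_predict",
    "wemisvm_train",
    "wemisvm_predict",
    "whole_image_features",
]


@dataclass(frozen=True)
class CitationConfig:
    """R = number of reference neighbours; C_cite = citer rank (the cited
    convention uses citers of rank R + 2)."""

    R: int = 2
    C_cite: int = 4

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ParameterError(f"R must be >= 1, got {self.R}")
        if self.C_cite < 1:
            raise ParameterError(f"C_cite must be >= 1, got {self.C_cite}")


def _features_of(bag: Bag) -> np.ndarray:
    if bag.n_i == 0:
        raise ValueError(f"bag {bag.bag_id} has no instances")
    return bag.feature_matrix()


def min_hausdorff_distance(bag_a: Bag, bag_b: Bag) -> float:
    """Smallest Euclidean distance between any instance pair of two bags."""
    fa, fb = _features_of(bag_a), _features_of(bag_b)
    return float(cdist(fa, fb).min())


def citation_knn_predict(
    train_bags: list[Bag], test_bag: Bag, config: CitationConfig | None = None
) -> int:
    """Majority vote of references and citers; ties go to -1 (non-malignant)."""
    config = config or CitationConfig()
    if len(train_bags) < config.R:
        raise ConfigurationError(
            f"need at least R={config.R} training bags, got {len(train_bags)}"
        )
    d_test = np.array([min_hausdorff_distance(b, test_bag) for b in train_bags])
    ref_idx = np.argsort(d_test, kind="stable")[: config.R]
    votes = [train_bags[i].label for i in ref_idx]
    # citers: training bags whose C_cite-nearest neighbourhood among the
    # remaining training bags plus the test bag includes the test bag
    n = len(train_bags)
    if n > 1:
        d_train = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = min_hausdorff_distance(train_bags[i], train_bags[j])
                d_train[i, j] = d_train[j, i] = d
    for i in range(n):
        others = np.concatenate(
            [np.delete(d_train[i], i), [d_test[i]]]
        ) if n > 1 else np.array([d_test[i]])
        rank = int(np.sum(others < d_test[i])) + 1  # 1-based, ties favour citing
        if rank <= config.C_cite:
            votes.append(train_bags[i].label)
    total = int(np.sum(votes))
    return 1 if total > 0 else -1


def wemisvm_train(
    train_bags: list[Bag],
    pso_config: PSOConfig | None = None,
    lo_config: LOConfig | None = None,
) -> TrainedClassifier:
    """Dissolve the bags (instances take bag labels) and fit one tuned SVM."""
    X = np.vstack([b.feature_matrix() for b in train_bags if b.n_i > 0])
    y = np.concatenate(
        [np.full(b.n_i, b.label) for b in train_bags if b.n_i > 0]
    )
    params, _ = tune_svm_params(X, y, pso_config, lo_config)
    return train_svm(X, y, params)


def wemisvm_predict(clf: TrainedClassifier, bag: Bag) -> int:
    """Bag label = sign of the mean instance decision value (0 -> +1)."""
    if bag.n_i == 0:
        raise PredictionError(f"bag {bag.bag_id} has no instances to predict")
    mean_dec = float(np.mean(clf.decision_values(bag.feature_matrix())))
    return 1 if mean_dec >= 0 else -1


def whole_image_features(img: np.ndarray, config: GLCMConfig | None = None) -> np.ndarray:
    """One GLCM feature vector for the full frame (same recipe as instances)."""
    return instance_features(img, config or GLCMConfig())
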