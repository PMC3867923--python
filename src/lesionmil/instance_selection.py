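"""Two-stage instance optimization and classifier construction.

Stage 1 (background removal): a block that contains no tissue is a single
constant gray level, so its angular second moment is exactly 1; any
instance whose mean d=1 ASM reaches 1 (within tolerance) is discarded.

Stage 2 (key-instance selection): instances inherit their bag's label, but
in positive bags most blocks are actually non-lesion tissue, so those weak
labels are noisy.  Instances are therefore scored by bag-level
cross-validation -- each fold is predicted by a tuned SVM trained on the
other folds' instances -- and only the correctly classified instances of
the bags with the highest per-bag accuracy (at or above a configurable
quantile) are retained.  These "excellent" instances form the key-instance
set, the deployable training set; members from positive bags carry the
selection flag ``a_j = 1``, members from negative bags ``a_j = 0``.

The final classifier is an RBF-SVM trained on the key-instance set, with
(C, g) tuned by PSO plus a local coordinate search on that same set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .bags import Bag, label_instances
from .errors import ConfigurationError, ParameterError, SelectionError, StateError
from .svm_tuning import (
    LOConfig,
    PSOConfig,
    SVMParams,
    TrainedClassifier,
    train_svm,
    tune_svm_params,
)
from .texture import GLCMConfig, feature_names

__all__ = [
    "IOConfig",
    "ScoredInstances",
    "KeyInstanceSet",
    "BuiltModel",
    "first_instance_optimization",
    "score_instances",
    "second_instance_optimization",
    "build_classifier",
]


@dataclass(frozen=True)
class IOConfig:
    """Instance-optimization settings.

    ``asm_tolerance``: an instance is background when its mean d=1 ASM is
    >= 1 - tolerance.  ``excellent_bag_quantile``: bags at or above this
    quantile of per-bag accuracy contribute key instances (0.5 = median).
    ``selection_folds``: bag-level CV folds for the scoring pass.
    ``strict_aj_mask``: if True, only rows with a_j = 1 train the final
    model (degenerate single-class set unless combined with other rows; the
    default keeps all key instances as training rows).
    """

    asm_tolerance: float = 1e-9
    excellent_bag_quantile: float = 0.5
    selection_folds: int = 5
    strict_aj_mask: bool = False

    def __post_init__(self) -> None:
        if self.asm_tolerance < 0:
            raise ParameterError(
                f"asm_tolerance must be >= 0, got {self.asm_tolerance}"
            )
        if not (0 < self.excellent_bag_quantile <= 1):
            raise ParameterError(
                "excellent_bag_quantile must lie in (0, 1], got "
                f"{self.excellent_bag_quantile}"
            )
        if self.selection_folds < 2:
            raise ParameterError(
                f"selection_folds must be >= 2, got {self.selection_folds}"
            )


def first_instance_optimization(
    bag: Bag, asm_tolerance: float = 1e-9, asm_index: int = 0
) -> Bag:
    """Drop background instances (mean d=1 ASM >= 1 - tolerance).

    Returns a new bag with the surviving instances in their original order;
    removed grid positions are recorded in ``removed_background``.
    ``asm_index`` is the position of the d=1 ASM mean in the feature layout
    (0 for the default layout).
    """
    if any(inst.features is None for inst in bag.instances):
        raise StateError(f"bag {bag.bag_id}: features must be computed before the first IO")
    kept, removed = [], list(bag.removed_background)
    for inst in bag.instances:
        if inst.features[asm_index] >= 1.0 - asm_tolerance:
            removed.append((inst.grid_row, inst.grid_col))
        else:
            kept.append(inst)
    return Bag(
        bag_id=bag.bag_id,
        label=bag.label,
        instances=kept,
        block_length=bag.block_length,
        removed_background=removed,
    )


@dataclass
class ScoredInstances:
    """Selection-pass output: per-instance correctness and per-bag accuracy."""

    bags: list[Bag]
    predicted: dict[str, np.ndarray]  # bag_id -> predicted labels per instance
    correct: dict[str, np.ndarray]  # bag_id -> boolean per instance
    bag_accuracy: dict[str, float]


def _deal_folds(bags: list[Bag], n_folds: int, rng) -> list[list[int]]:
    """Stratified round-robin fold assignment of bag indices."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for lab in (1, -1):
        idx = [i for i, b in enumerate(bags) if b.label == lab]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    return folds


def score_instances(
    bags: list[Bag],
    io_config: IOConfig | None = None,
    pso_config: PSOConfig | None = None,
    lo_config: LOConfig | None = None,
    seed: int = 0,
) -> ScoredInstances:
    """Score every instance by bag-level cross-validation.

    All instances of a bag share a fold, so no instance is ever scored by a
    model that saw it (or its bag) during training.  Each fold is predicted
    by an RBF-SVM whose (C, g) were tuned on the remaining folds.
    """
    io_config = io_config or IOConfig()
    pso_config = pso_config or PSOConfig()
    lo_config = lo_config or LOConfig()
    bags = [b for b in bags if b.n_i > 0]
    labels = {b.label for b in bags}
    if len(bags) < 2 or labels != {1, -1}:
        raise ConfigurationError(
            "instance scoring needs at least two bags covering both classes"
        )
    n_folds = min(io_config.selection_folds, len(bags))
    ss = SeedSequence(seed)
    deal_seeds = ss.spawn(10)
    folds = None
    for attempt in range(10):
        candidate = _deal_folds(bags, n_folds, default_rng(deal_seeds[attempt]))
        ok = True
        for f in range(n_folds):
            train_labels = {
                bags[i].label for g in range(n_folds) if g != f for i in candidate[g]
            }
            if train_labels != {1, -1}:
                ok = False
                break
        if ok:
            folds = candidate
            break
    if folds is None:
        raise ConfigurationError(
            "could not deal folds with both classes on every training side; "
            "reduce selection_folds or add bags"
        )

    fold_seeds = ss.spawn(n_folds)
    predicted: dict[str, np.ndarray] = {}
    correct: dict[str, np.ndarray] = {}
    for f in range(n_folds):
        train_idx = [i for g in range(n_folds) if g != f for i in folds[g]]
        X_tr = np.vstack([bags[i].feature_matrix() for i in train_idx])
        y_tr = np.concatenate(
            [np.full(bags[i].n_i, bags[i].label) for i in train_idx]
        )
        fold_seed = int(fold_seeds[f].generate_state(1)[0] % (2**31))
        fold_pso = _reseed(pso_config, fold_seed, y_tr)
        params, _ = _tune_or_fallback(X_tr, y_tr, fold_pso, lo_config)
        clf = train_svm(X_tr, y_tr, params)
        for i in folds[f]:
            preds = clf.predict(bags[i].feature_matrix())
            predicted[bags[i].bag_id] = preds
            correct[bags[i].bag_id] = preds == bags[i].label
    bag_accuracy = {
        b.bag_id: float(np.mean(correct[b.bag_id])) for b in bags
    }
    return ScoredInstances(
        bags=bags, predicted=predicted, correct=correct, bag_accuracy=bag_accuracy
    )


def _reseed(pso_config: PSOConfig, seed: int, y=None) -> PSOConfig:
    """Derive a seeded PSO config; fold count never exceeds the minority
    class count of ``y`` (stratified CV needs that many members per fold)."""
    from dataclasses import replace

    folds = pso_config.fitness_folds
    if y is not None:
        _, counts = np.unique(y, return_counts=True)
        folds = max(2, min(folds, int(counts.min())))
    return replace(pso_config, seed=seed, fitness_folds=folds)


def _tune_or_fallback(
    X: np.ndarray, y: np.ndarray, pso_config: PSOConfig, lo_config: LOConfig
) -> tuple[SVMParams, dict]:
    """CPSO tuning, or box-center parameters when the minority class is too
    small to cross-validate at all."""
    _, counts = np.unique(y, return_counts=True)
    if int(counts.min()) >= 2:
        return tune_svm_params(X, y, pso_config, lo_config)
    params = SVMParams(
        C=float(np.sqrt(pso_config.c_bounds[0] * pso_config.c_bounds[1])),
        g=float(np.sqrt(pso_config.g_bounds[0] * pso_config.g_bounds[1])),
    )
    return params, {"degenerate": "minority class too small for CV tuning"}


@dataclass
class KeyInstanceSet:
    """The retained "excellent" instances -- the deployable training set."""

    X: np.ndarray
    y: np.ndarray
    bag_ids: list[str]
    grid_positions: list[tuple[int, int]]
    a_j: np.ndarray
    bag_accuracy: dict[str, float]
    accuracy_thresholds: dict[int, float]

    def __len__(self) -> int:
        return self.X.shape[0]

    def training_arrays(self, strict_aj_mask: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and labels for the final fit.

        With ``strict_aj_mask`` only a_j = 1 rows are returned; the default
        keeps every key instance (an SVM needs both classes).
        """
        if not strict_aj_mask:
            return self.X, self.y
        mask = self.a_j == 1
        return self.X[mask], self.y[mask]

    def to_frame(self) -> pd.DataFrame:
        cols = feature_names()
        if self.X.shape[1] != len(cols):
            cols = [f"f{i}" for i in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "bag_id", self.bag_ids)
        df.insert(1, "grid_row", [rc[0] for rc in self.grid_positions])
        df.insert(2, "grid_col", [rc[1] for rc in self.grid_positions])
        df.insert(3, "label", self.y)
        df.insert(4, "a_j", self.a_j)
        return df

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def second_instance_optimization(
    scored: ScoredInstances, io_config: IOConfig | None = None
) -> KeyInstanceSet:
    """Retain correctly classified instances from high-accuracy bags.

    "High accuracy" bags are those at or above the configured quantile of
    the per-bag accuracy distribution *within their own class*: positive
    bags carry mostly non-lesion blocks with borrowed positive labels, so
    their attainable accuracy is structurally lower than negative bags';
    a pooled quantile would often retain no positive bag at all and leave
    the training set single-class.  Raising the quantile never enlarges
    the result.
    """
    io_config = io_config or IOConfig()
    thresholds: dict[int, float] = {}
    for lab in (1, -1):
        accs = [scored.bag_accuracy[b.bag_id] for b in scored.bags if b.label == lab]
        if accs:
            thresholds[lab] = float(
                np.quantile(accs, io_config.excellent_bag_quantile)
            )
    rows_X, rows_y, bag_ids, grid, aj = [], [], [], [], []
    for b in scored.bags:
        if scored.bag_accuracy[b.bag_id] < thresholds[b.label]:
            continue
        mask = scored.correct[b.bag_id]
        for inst, ok in zip(b.instances, mask):
            if not ok:
                continue
            inst.a_j = 1 if b.label == 1 else 0
            rows_X.append(inst.features)
            rows_y.append(b.label)
            bag_ids.append(b.bag_id)
            grid.append((inst.grid_row, inst.grid_col))
            aj.append(inst.a_j)
    if not rows_X:
        raise SelectionError(
            "no bag qualified as excellent; lower excellent_bag_quantile"
        )
    # backstop: if a class contributed no correctly classified instance at
    # all (every bag of that class scored 0), keep its best bag wholesale --
    # a training set must still represent both classes
    for lab in (1, -1):
        if lab in thresholds and not any(y == lab for y in rows_y):
            best = max(
                (b for b in scored.bags if b.label == lab),
                key=lambda b: scored.bag_accuracy[b.bag_id],
            )
            for inst in best.instances:
                inst.a_j = 1 if lab == 1 else 0
                rows_X.append(inst.features)
                rows_y.append(lab)
                bag_ids.append(best.bag_id)
                grid.append((inst.grid_row, inst.grid_col))
                aj.append(inst.a_j)
    return KeyInstanceSet(
        X=np.vstack(rows_X),
        y=np.asarray(rows_y, dtype=int),
        bag_ids=bag_ids,
        grid_positions=grid,
        a_j=np.asarray(aj, dtype=int),
        bag_accuracy=dict(scored.bag_accuracy),
        accuracy_thresholds=thresholds,
    )


@dataclass
class BuiltModel:
    """Trained bag classifier: decision function, key instances, threshold."""

    classifier: TrainedClassifier
    key_instances: KeyInstanceSet
    params: SVMParams
    threshold: float
    tuning_report: dict = field(default_factory=dict)


def build_classifier(
    training_bags: list[Bag],
    io_config: IOConfig | None = None,
    pso_config: PSOConfig | None = None,
    lo_config: LOConfig | None = None,
    threshold: float = 0.86,
    seed: int = 0,
) -> BuiltModel:
    """Full classifier construction from labeled, featured training bags.

    Pipeline: label instances with bag labels -> first instance
    optimization (background removal) -> cross-validated instance scoring
    -> second instance optimization (key-instance set) -> PSO + local
    search for (C, g) on the key instances -> final RBF-SVM fit.
    """
    io_config = io_config or IOConfig()
    pso_config = pso_config or PSOConfig()
    lo_config = lo_config or LOConfig()
    prepared = []
    for bag in training_bags:
        bag = label_instances(bag)
        prepared.append(first_instance_optimization(bag, io_config.asm_tolerance))
    ss = SeedSequence(seed)
    score_seed, tune_seed = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)
    )
    scored = score_instances(prepared, io_config, pso_config, lo_config, seed=score_seed)
    keyset = second_instance_optimization(scored, io_config)
    X, y = keyset.training_arrays(io_config.strict_aj_mask)
    final_pso = _reseed(pso_config, tune_seed, y)
    params, report = _tune_or_fallback(X, y, final_pso, lo_config)
    clf = train_svm(X, y, params)
    return BuiltModel(
        classifier=clf,
        key_instances=keyset,
        params=params,
        threshold=threshold,
        tuning_report=report,
    )
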