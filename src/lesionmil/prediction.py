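"""Threshold-based bag prediction and classification metrics.

A test bag is predicted by classifying each instance that survives the
background (ASM) filter and computing the fraction ``r`` of instances
predicted negative.  The bag is negative when ``r`` strictly exceeds the
threshold ``P`` (default 0.86), otherwise positive: since only a few blocks
of a lesion-bearing image actually contain lesion, a positive bag is one
where *enough* instances deviate from the non-malignant pattern, and P
lives in [0.5, 1].

Metrics follow the usual confusion-matrix definitions with the lesion
(cancer) class as positive: ACC = (TP+TN)/all, SEN = TP/(TP+FN),
SPE = TN/(TN+FP).  Ratios with empty denominators are reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .bags import Bag
from .errors import ParameterError, PredictionError
from .instance_selection import first_instance_optimization
from .svm_tuning import TrainedClassifier

__all__ = [
    "PredictorConfig",
    "BagPrediction",
    "ConfusionCounts",
    "EvalReport",
    "predict_bag",
    "evaluate",
    "mean_report",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Bag-level decision settings.

    ``P`` is the negative-ratio threshold in [0.5, 1]; ``block_length`` and
    ``asm_tolerance`` record the tiling and background-filter settings the
    classifier was built with.
    """

    P: float = 0.86
    block_length: float = 113.0
    asm_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not (0.5 <= self.P <= 1.0):
            raise ParameterError(f"P must lie in [0.5, 1], got {self.P}")
        if self.block_length < 1:
            raise ParameterError(
                f"block_length must be >= 1, got {self.block_length}"
            )
        if self.asm_tolerance < 0:
            raise ParameterError(
                f"asm_tolerance must be >= 0, got {self.asm_tolerance}"
            )


class BagPrediction(NamedTuple):
    label: int
    negative_ratio: float
    n_reserved: int
    instance_labels: np.ndarray


def predict_bag(
    clf: TrainedClassifier, bag: Bag, config: PredictorConfig | None = None
) -> BagPrediction:
    """Predict one bag; background instances are excluded before the ratio.

    ``r`` = (#instances predicted -1) / (#reserved instances); the bag is
    negative iff r > P (strict), so r exactly equal to P yields +1.
    """
    config = config or PredictorConfig()
    reserved = first_instance_optimization(bag, config.asm_tolerance)
    if reserved.n_i == 0:
        raise PredictionError(
            f"bag {bag.bag_id}: every instance is background; cannot predict"
        )
    preds = clf.predict(reserved.feature_matrix())
    r = float(np.mean(preds == -1))
    label = -1 if r > config.P else 1
    return BagPrediction(
        label=label, negative_ratio=r, n_reserved=reserved.n_i, instance_labels=preds
    )


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ParameterError("confusion counts must be non-negative")


@dataclass
class EvalReport:
    counts: ConfusionCounts
    ACC: float | None
    SEN: float | None
    SPE: float | None
    per_group: list["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "TP": self.counts.TP,
            "FN": self.counts.FN,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "ACC": self.ACC,
            "SEN": self.SEN,
            "SPE": self.SPE,
        }
        if self.per_group:
            d["per_group"] = [g.to_dict() for g in self.per_group]
        return d


def evaluate(predicted: Sequence[int], truth: Sequence[int]) -> EvalReport:
    """Confusion counts and ACC/SEN/SPE; the +1 (lesion) class is positive."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ParameterError(
            f"predicted {predicted.shape} and truth {truth.shape} differ in length"
        )
    for name, arr in (("predicted", predicted), ("truth", truth)):
        bad = set(np.unique(arr)) - {1, -1}
        if bad:
            raise ParameterError(f"{name} labels must be +1/-1, found {sorted(bad)}")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == -1)))
    tn = int(np.sum((truth == -1) & (predicted == -1)))
    fp = int(np.sum((truth == -1) & (predicted == 1)))
    counts = ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)
    total = tp + fn + tn + fp
    acc = (tp + tn) / total if total else None
    sen = tp / (tp + fn) if (tp + fn) else None
    spe = tn / (tn + fp) if (tn + fp) else None
    return EvalReport(counts=counts, ACC=acc, SEN=sen, SPE=spe)


def mean_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Unweighted mean of ACC/SEN/SPE across groups (None entries skipped);
    counts are summed for reference."""
    if not reports:
        raise ParameterError("mean_report needs at least one report")
    counts = ConfusionCounts(
        TP=sum(r.counts.TP for r in reports),
        FN=sum(r.counts.FN for r in reports),
        TN=sum(r.counts.TN for r in reports),
        FP=sum(r.counts.FP for r in reports),
    )

    def avg(values):
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    return EvalReport(
        counts=counts,
        ACC=avg([r.ACC for r in reports]),
        SEN=avg([r.SEN for r in reports]),
        SPE=avg([r.SPE for r in reports]),
        per_group=list(reports),
    )
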