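"""End-to-end orchestration: dataset -> bags -> training -> validation.

Implements the evaluation protocol used throughout the package: each class
is split 50/50 into a training and a testing half; the classifier is built
on the training half; the testing half is dealt into five stratified
groups, each evaluated separately; and the reported figures are the
unweighted means of the five groups' ACC/SEN/SPE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import baselines
from .bags import Bag, compute_bag_features, extract_instances
from .config import ExperimentConfig
from .errors import ConfigurationError
from .instance_selection import BuiltModel, build_classifier, first_instance_optimization
from .phantoms import PhantomSample, generate_dataset, read_manifest
from .prediction import EvalReport, evaluate, mean_report, predict_bag
from .preprocessing import preprocess, read_image
from .svm_tuning import train_svm, tune_svm_params

__all__ = [
    "LabeledImage",
    "prepare_bag",
    "five_group_validation",
    "ValidationResult",
    "compare_methods",
    "run_experiment",
    "sweep",
    "load_manifest_samples",
]


@dataclass
class LabeledImage:
    """A raw image with its bag label and class name."""

    image: np.ndarray
    bag_label: int
    class_name: str
    sample_id: str


def from_phantoms(samples: list[PhantomSample], prefix: str = "s") -> list[LabeledImage]:
    return [
        LabeledImage(
            image=s.image,
            bag_label=s.bag_label,
            class_name=s.class_name,
            sample_id=f"{prefix}{i:04d}_{s.class_name}",
        )
        for i, s in enumerate(samples)
    ]


def load_manifest_samples(manifest_path: str | Path) -> list[LabeledImage]:
    """Read every image referenced by a dataset manifest."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    out = []
    for i, row in df.iterrows():
        out.append(
            LabeledImage(
                image=read_image(root / row["path"]),
                bag_label=int(row["label"]),
                class_name=str(row["class"]),
                sample_id=Path(row["path"]).stem,
            )
        )
    return out


def prepare_bag(sample: LabeledImage, cfg: ExperimentConfig) -> Bag:
    """Preprocess, tile, and featurize one image into a labeled bag."""
    img = preprocess(sample.image, cfg.preprocess)
    bag = extract_instances(
        img, cfg.block_length, bag_id=sample.sample_id, label=sample.bag_label
    )
    return compute_bag_features(bag, cfg.glcm)


def _stratified_half_split(
    samples: list[LabeledImage], rng
) -> tuple[list[int], list[int]]:
    train_idx, test_idx = [], []
    classes = sorted({s.class_name for s in samples})
    for cname in classes:
        idx = [i for i, s in enumerate(samples) if s.class_name == cname]
        if len(idx) < 2:
            raise ConfigurationError(
                f"class {cname!r} has {len(idx)} samples; cannot split 50/50"
            )
        idx = [idx[j] for j in rng.permutation(len(idx))]
        n_train = len(idx) // 2
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return train_idx, test_idx


def _deal_groups(labels: list[int], n_groups: int, rng) -> list[list[int]]:
    """Stratified round-robin dealing of test indices into groups."""
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            groups[j % n_groups].append(i)
    return groups


@dataclass
class ValidationResult:
    report: EvalReport
    group_reports: list[EvalReport]
    model: BuiltModel
    predictions: pd.DataFrame


def five_group_validation(
    samples: list[LabeledImage], cfg: ExperimentConfig | None = None
) -> ValidationResult:
    """Train on a stratified half, evaluate on five stratified test groups.

    Returns the averaged report, the per-group reports, the trained model,
    and a per-bag prediction table (bag_id, negative ratio, prediction,
    truth, group).
    """
    cfg = cfg or ExperimentConfig()
    ss = SeedSequence(cfg.seed)
    split_rng, group_rng = (default_rng(c) for c in ss.spawn(2))
    build_seed = cfg.stage_seed(2)

    train_idx, test_idx = _stratified_half_split(samples, split_rng)
    train_bags = [prepare_bag(samples[i], cfg) for i in train_idx]
    model = build_classifier(
        train_bags,
        io_config=cfg.io,
        pso_config=cfg.pso,
        lo_config=cfg.lo,
        threshold=cfg.predictor.P,
        seed=build_seed,
    )

    test_labels = [samples[i].bag_label for i in test_idx]
    groups = _deal_groups(test_labels, cfg.validation_groups, group_rng)
    group_reports = []
    rows = []
    for g, members in enumerate(groups):
        preds, truths = [], []
        for m in members:
            i = test_idx[m]
            bag = prepare_bag(samples[i], cfg)
            bp = predict_bag(model.classifier, bag, cfg.predictor)
            preds.append(bp.label)
            truths.append(samples[i].bag_label)
            rows.append(
                {
                    "bag_id": samples[i].sample_id,
                    "group": g,
                    "negative_ratio": bp.negative_ratio,
                    "prediction": bp.label,
                    "truth": samples[i].bag_label,
                }
            )
        group_reports.append(evaluate(preds, truths))
    report = mean_report(group_reports)
    return ValidationResult(
        report=report,
        group_reports=group_reports,
        model=model,
        predictions=pd.DataFrame(rows),
    )


def compare_methods(
    samples: list[LabeledImage],
    cfg: ExperimentConfig | None = None,
    methods: tuple[str, ...] | None = None,
    citation_config: baselines.CitationConfig | None = None,
) -> dict[str, EvalReport]:
    """Evaluate the MIL classifier and the baselines under one shared split."""
    cfg = cfg or ExperimentConfig()
    methods = methods or cfg.methods
    citation_config = citation_config or baselines.CitationConfig()
    ss = SeedSequence(cfg.seed)
    split_rng, group_rng = (default_rng(c) for c in ss.spawn(2))
    build_seed = cfg.stage_seed(2)

    train_idx, test_idx = _stratified_half_split(samples, split_rng)
    test_labels = [samples[i].bag_label for i in test_idx]
    groups = _deal_groups(test_labels, cfg.validation_groups, group_rng)

    need_bags = set(methods) - {"svm"}
    train_bags = test_bags = None
    if need_bags:
        train_bags = [prepare_bag(samples[i], cfg) for i in train_idx]
        test_bags = [prepare_bag(samples[i], cfg) for i in test_idx]

    results: dict[str, EvalReport] = {}

    def grouped_report(pred_by_test_pos: list[int]) -> EvalReport:
        reports = []
        for members in groups:
            preds = [pred_by_test_pos[m] for m in members]
            truths = [test_labels[m] for m in members]
            reports.append(evaluate(preds, truths))
        return mean_report(reports)

    for method in methods:
        if method == "iomil":
            model = build_classifier(
                [replace_bag(b) for b in train_bags],
                io_config=cfg.io,
                pso_config=cfg.pso,
                lo_config=cfg.lo,
                threshold=cfg.predictor.P,
                seed=build_seed,
            )
            preds = [
                predict_bag(model.classifier, b, cfg.predictor).label for b in test_bags
            ]
        elif method == "svm":
            X_tr = np.vstack(
                [
                    baselines.whole_image_features(
                        preprocess(samples[i].image, cfg.preprocess), cfg.glcm
                    )
                    for i in train_idx
                ]
            )
            y_tr = np.array([samples[i].bag_label for i in train_idx])
            pso = replace(cfg.pso, seed=cfg.stage_seed(3))
            params, _ = tune_svm_params(X_tr, y_tr, pso, cfg.lo)
            clf = train_svm(X_tr, y_tr, params)
            X_te = np.vstack(
                [
                    baselines.whole_image_features(
                        preprocess(samples[i].image, cfg.preprocess), cfg.glcm
                    )
                    for i in test_idx
                ]
            )
            preds = list(clf.predict(X_te))
        elif method == "citation-knn":
            reserved_train = [
                first_instance_optimization(b, cfg.io.asm_tolerance) for b in train_bags
            ]
            reserved_train = [b for b in reserved_train if b.n_i > 0]
            preds = [
                baselines.citation_knn_predict(
                    reserved_train,
                    first_instance_optimization(b, cfg.io.asm_tolerance),
                    citation_config,
                )
                for b in test_bags
            ]
        elif method == "wemisvm":
            reserved_train = [
                first_instance_optimization(replace_bag(b), cfg.io.asm_tolerance)
                for b in train_bags
            ]
            pso = replace(cfg.pso, seed=cfg.stage_seed(4))
            clf = baselines.wemisvm_train(reserved_train, pso, cfg.lo)
            preds = [
                baselines.wemisvm_predict(
                    clf, first_instance_optimization(b, cfg.io.asm_tolerance)
                )
                for b in test_bags
            ]
        else:  # pragma: no cover - validated upstream
            raise ConfigurationError(f"unknown method {method!r}")
        results[method] = grouped_report(preds)
    return results


def replace_bag(bag: Bag) -> Bag:
    """Fresh labeled copy so per-method mutation (instance labels, a_j)
    cannot leak between methods."""
    import copy

    new = copy.deepcopy(bag)
    for inst in new.instances:
        inst.label = new.label
    return new


def run_experiment(
    cfg: ExperimentConfig,
    samples: list[LabeledImage] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate (if needed), validate, and write JSON/CSV reports."""
    if samples is None:
        phantom_samples, _ = generate_dataset(
            cfg.per_class_counts, cfg.phantom_overrides, master_seed=cfg.stage_seed(0)
        )
        samples = from_phantoms(phantom_samples)
    if set(cfg.methods) == {"iomil"} or cfg.methods == ("iomil",):
        result = five_group_validation(samples, cfg)
        reports = {"iomil": result.report}
        predictions = result.predictions
    else:
        reports = compare_methods(samples, cfg)
        predictions = None
    payload = {
        "config": cfg.to_dict(),
        "reports": {m: r.to_dict() for m, r in reports.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(payload, indent=1, default=str))
        if predictions is not None:
            predictions.to_csv(out_dir / "predictions.csv", index=False)
    return payload


def sweep(
    cfg: ExperimentConfig,
    parameter: str,
    grid: list[float],
    samples: list[LabeledImage] | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline along a parameter grid with shared seeds.

    ``P`` varies only the bag-decision threshold (one trained model, shared
    across the grid); ``block_length`` retrains per point; ``C``/``g``
    sweep the cross-validated key-instance fitness at the tuned value of
    the other parameter, mirroring the local search's line sweeps.
    """
    if parameter not in ("block_length", "P", "C", "g"):
        raise ConfigurationError(
            f"parameter must be one of block_length, P, C, g; got {parameter!r}"
        )
    if samples is None:
        phantom_samples, _ = generate_dataset(
            cfg.per_class_counts, cfg.phantom_overrides, master_seed=cfg.stage_seed(0)
        )
        samples = from_phantoms(phantom_samples)
    rows = []
    if parameter == "P":
        result = five_group_validation(samples, cfg)
        ratios = result.predictions["negative_ratio"].to_numpy()
        truths = result.predictions["truth"].to_numpy()
        groups = result.predictions["group"].to_numpy()
        for P in grid:
            preds = np.where(ratios > P, -1, 1)
            reports = [
                evaluate(preds[groups == g], truths[groups == g])
                for g in sorted(set(groups))
            ]
            rep = mean_report(reports)
            rows.append(
                {
                    "P": P,
                    "ACC": rep.ACC,
                    "SEN": rep.SEN,
                    "SPE": rep.SPE,
                    "n_negative_predictions": int(np.sum(preds == -1)),
                }
            )
    elif parameter == "block_length":
        for L in grid:
            cfg_L = replace(cfg, block_length=float(L),
                            predictor=replace(cfg.predictor, block_length=float(L)))
            result = five_group_validation(samples, cfg_L)
            n_instances = int(
                np.mean([prepare_bag(samples[i], cfg_L).n_i for i in range(min(3, len(samples)))])
            )
            rows.append(
                {
                    "block_length": L,
                    "ACC": result.report.ACC,
                    "SEN": result.report.SEN,
                    "SPE": result.report.SPE,
                    "instances_per_bag": n_instances,
                }
            )
    else:  # C or g sweeps of the key-instance CV fitness
        result = five_group_validation(samples, cfg)
        keyset = result.model.key_instances
        X, y = keyset.training_arrays(cfg.io.strict_aj_mask)
        from .svm_tuning import make_cv_fitness

        fitness = make_cv_fitness(X, y, cfg.pso.fitness_folds, cfg.stage_seed(5))
        best = result.model.params
        for v in grid:
            if parameter == "C":
                fit = fitness(float(v), best.g)
            else:
                fit = fitness(best.C, float(v))
            rows.append({parameter: v, "cv_accuracy": fit})
    return pd.DataFrame(rows)
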