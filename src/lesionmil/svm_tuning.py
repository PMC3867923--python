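"""RBF-SVM training and combined PSO + local-search hyperparameter tuning.

The classifier is a soft-margin RBF support vector machine; the decision
function is ``f(x) = sgn(sum_i w_i* y_i K(x_i, x) + b*)`` with dual weights
bounded by the penalty ``C`` and kernel ``K(x, x') = exp(-g ||x - x'||^2)``.
The quadratic-programming dual is delegated to scikit-learn's libsvm
wrapper; this module owns the tuning strategy:

1. global-best particle swarm optimization of ``(log2 C, log2 g)`` against a
   stratified cross-validation accuracy fitness, then
2. a coordinate line search around the PSO optimum -- sweep C at fixed g,
   keep the best (ties resolved toward smaller C), then sweep g at the kept
   C (ties toward smaller g).

The combination never returns a point with lower CV fitness than the PSO
result, because both sweeps include their starting value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.random import default_rng
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, ParameterError

__all__ = [
    "SVMParams",
    "TrainedClassifier",
    "PSOConfig",
    "LOConfig",
    "train_svm",
    "predict_instances",
    "make_cv_fitness",
    "pso_optimize",
    "local_optimize",
    "tune_svm_params",
]

FitnessFn = Callable[[float, float], float]


@dataclass(frozen=True)
class SVMParams:
    """Penalty factor C and RBF control factor g, both strictly positive."""

    C: float
    g: float

    def __post_init__(self) -> None:
        for name, v in (("C", self.C), ("g", self.g)):
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")


class TrainedClassifier:
    """A fitted RBF-SVM decision function.

    Input features are standardized (zero mean, unit variance, statistics
    from the training rows) before the kernel; the GLCM statistics live on
    wildly different scales (ASM in (0, 1], contrast up to thousands) and a
    shared RBF width is meaningless without this.  The dual representation
    (support vectors in the standardized space, signed dual weights
    ``w_i* y_i``, bias ``b*``) is exposed so the decision values can be
    recomputed independently of the solver; use :meth:`transform` to map
    probes into the kernel's input space.
    """

    def __init__(self, svc: SVC, scaler: StandardScaler, params: SVMParams, n_train: int):
        self._svc = svc
        self._scaler = scaler
        self.params = params
        self.n_train = n_train

    @property
    def support_vectors(self) -> np.ndarray:
        return self._svc.support_vectors_

    @property
    def signed_dual_weights(self) -> np.ndarray:
        """w_i* y_i for each support vector (|value| <= C)."""
        return self._svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self._svc.intercept_[0])

    @property
    def n_features(self) -> int:
        return self._svc.support_vectors_.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map raw feature rows into the standardized kernel input space."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ParameterError(
                f"expected feature matrix with {self.n_features} columns, got shape {X.shape}"
            )
        return self._scaler.transform(X)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign of the decision value; exact zero maps to +1."""
        return np.where(self.decision_values(X) >= 0, 1, -1)


def train_svm(
    X: np.ndarray, y: Sequence[int], params: SVMParams
) -> TrainedClassifier:
    """Fit a soft-margin RBF-SVM on feature rows X with labels in {+1, -1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ParameterError(f"X {X.shape} and y {y.shape} are inconsistent")
    if not np.isfinite(X).all():
        raise ParameterError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training data contains a single class")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="rbf", C=params.C, gamma=params.g)
    svc.fit(scaler.transform(X), y)
    return TrainedClassifier(svc, scaler, params, n_train=X.shape[0])


def predict_instances(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Instance labels in {+1, -1} (decision value 0 -> +1)."""
    return clf.predict(X)


def make_cv_fitness(
    X: np.ndarray, y: Sequence[int], folds: int = 5, seed: int = 0
) -> FitnessFn:
    """Stratified k-fold CV accuracy of an RBF-SVM as a function of (C, g).

    The fold assignment is fixed once, so every candidate is scored on the
    same splits and the fitness landscape is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigurationError("fitness requires two classes")
    if folds < 2 or folds > counts.min():
        raise ConfigurationError(
            f"fitness_folds={folds} exceeds the minority-class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = [(tr, te) for tr, te in skf.split(X, y)]
    cache: dict[tuple[float, float], float] = {}

    def fitness(C: float, g: float) -> float:
        key = (float(C), float(g))
        if key in cache:
            return cache[key]
        accs = []
        for tr, te in splits:
            scaler = StandardScaler().fit(X[tr])
            svc = SVC(kernel="rbf", C=C, gamma=g).fit(scaler.transform(X[tr]), y[tr])
            accs.append(
                float(np.mean(svc.predict(scaler.transform(X[te])) == y[te]))
            )
        value = float(np.mean(accs))
        cache[key] = value
        return value

    return fitness


@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO settings; the search runs in (log2 C, log2 g) space."""

    swarm_size: int = 20
    iterations: int = 50
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    c_bounds: tuple[float, float] = (2.0**-2, 2.0**7)
    g_bounds: tuple[float, float] = (2.0**-4, 2.0**4)
    fitness_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ParameterError(f"swarm_size must be >= 1, got {self.swarm_size}")
        if self.iterations < 1:
            raise ParameterError(f"iterations must be >= 1, got {self.iterations}")
        for name, (lo, hi) in (("c_bounds", self.c_bounds), ("g_bounds", self.g_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ParameterError(f"{name} must be finite with 0 < lower < upper")
        if self.fitness_folds < 2:
            raise ParameterError(f"fitness_folds must be >= 2, got {self.fitness_folds}")


@dataclass(frozen=True)
class LOConfig:
    """Coordinate line-search settings (raw C/g units around the start)."""

    c_step: float = 0.05
    g_step: float = 0.05
    c_halfwidth: float = 1.0
    g_halfwidth: float = 3.5

    def __post_init__(self) -> None:
        for name, v in (
            ("c_step", self.c_step),
            ("g_step", self.g_step),
            ("c_halfwidth", self.c_halfwidth),
            ("g_halfwidth", self.g_halfwidth),
        ):
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")


def pso_optimize(
    X: np.ndarray | None,
    y: Sequence[int] | None,
    config: PSOConfig | None = None,
    fitness: FitnessFn | None = None,
) -> tuple[SVMParams, list[float]]:
    """Global-best PSO over (log2 C, log2 g); returns the best parameters and
    the per-iteration best-fitness trace (nondecreasing by construction)."""
    config = config or PSOConfig()
    if fitness is None:
        fitness = make_cv_fitness(X, y, config.fitness_folds, config.seed)
    rng = default_rng(config.seed)
    lo = np.log2([config.c_bounds[0], config.g_bounds[0]])
    hi = np.log2([config.c_bounds[1], config.g_bounds[1]])
    span = hi - lo
    n = config.swarm_size
    pos = lo + rng.uniform(0, 1, size=(n, 2)) * span
    vel = rng.uniform(-0.25, 0.25, size=(n, 2)) * span

    def eval_at(p: np.ndarray) -> float:
        return fitness(float(2.0 ** p[0]), float(2.0 ** p[1]))

    pbest = pos.copy()
    pbest_fit = np.array([eval_at(p) for p in pos])
    g_idx = int(np.argmax(pbest_fit))
    gbest = pbest[g_idx].copy()
    gbest_fit = float(pbest_fit[g_idx])
    trace = [gbest_fit]

    T = config.iterations
    for t in range(T):
        w = config.inertia_start + (config.inertia_end - config.inertia_start) * (
            t / max(T - 1, 1)
        )
        r1 = rng.uniform(size=(n, 2))
        r2 = rng.uniform(size=(n, 2))
        vel = (
            w * vel
            + config.c1 * r1 * (pbest - pos)
            + config.c2 * r2 * (gbest[None, :] - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        for i in range(n):
            f = eval_at(pos[i])
            if f > pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = pos[i]
                if f > gbest_fit:
                    gbest_fit = f
                    gbest = pos[i].copy()
        trace.append(gbest_fit)
    return SVMParams(C=float(2.0 ** gbest[0]), g=float(2.0 ** gbest[1])), trace


def _line_search(
    fitness: FitnessFn,
    fixed: float,
    start: float,
    step: float,
    halfwidth: float,
    sweep_first_arg: bool,
) -> tuple[float, list[tuple[float, float]]]:
    """Sweep one coordinate over start +/- halfwidth; ties -> smallest value."""
    n = int(round(halfwidth / step))
    values = [start + i * step for i in range(-n, n + 1)]
    values = [v for v in values if v > 1e-8]
    best_v, best_f = None, -np.inf
    table = []
    for v in sorted(values):
        f = fitness(v, fixed) if sweep_first_arg else fitness(fixed, v)
        table.append((v, f))
        if f > best_f:  # strict: first (smallest) maximizer wins ties
            best_f, best_v = f, v
    return best_v, table


def local_optimize(
    start: SVMParams,
    X: np.ndarray | None = None,
    y: Sequence[int] | None = None,
    config: LOConfig | None = None,
    fitness: FitnessFn | None = None,
    fitness_folds: int = 5,
    seed: int = 0,
    return_tables: bool = False,
):
    """Coordinate line search around ``start``: C sweep at fixed g, then g
    sweep at the kept C.  The start point is on both grids, so the returned
    CV fitness is never below the start's."""
    config = config or LOConfig()
    if fitness is None:
        fitness = make_cv_fitness(X, y, fitness_folds, seed)
    best_c, c_table = _line_search(
        fitness, start.g, start.C, config.c_step, config.c_halfwidth, True
    )
    best_g, g_table = _line_search(
        fitness, best_c, start.g, config.g_step, config.g_halfwidth, False
    )
    params = SVMParams(C=best_c, g=best_g)
    if return_tables:
        return params, {"C_sweep": c_table, "g_sweep": g_table}
    return params


def tune_svm_params(
    X: np.ndarray,
    y: Sequence[int],
    pso_config: PSOConfig | None = None,
    lo_config: LOConfig | None = None,
) -> tuple[SVMParams, dict]:
    """PSO followed by the local coordinate search, sharing one CV fitness."""
    pso_config = pso_config or PSOConfig()
    lo_config = lo_config or LOConfig()
    fitness = make_cv_fitness(X, y, pso_config.fitness_folds, pso_config.seed)
    pso_params, trace = pso_optimize(X, y, pso_config, fitness=fitness)
    lo_params, tables = local_optimize(
        pso_params, config=lo_config, fitness=fitness, return_tables=True
    )
    report = {
        "pso": {"best_C": pso_params.C, "best_g": pso_params.g, "trace": trace},
        "lo": {
            "best_C": lo_params.C,
            "best_g": lo_params.g,
            "fitness": fitness(lo_params.C, lo_params.g),
            "sweep_tables": tables,
        },
    }
    return lo_params, report
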