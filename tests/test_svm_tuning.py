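"""SVM training, decision-function fidelity, and PSO + local-search tuning."""

import numpy as np
import pytest

from lesionmil.errors import ConfigurationError, ParameterError
from lesionmil.svm_tuning import (
    LOConfig,
    PSOConfig,
    SVMParams,
    local_optimize,
    make_cv_fitness,
    predict_instances,
    pso_optimize,
    train_svm,
    tune_svm_params,
)


def blobs(n_per_class=20, sep=4.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0, noise, size=(n_per_class, 2)),
            rng.normal(sep, noise, size=(n_per_class, 2)),
        ]
    )
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    return X, y


def test_two_point_problem_both_support_vectors():
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    y = np.array([-1, 1])
    clf = train_svm(X, y, SVMParams(C=1.0, g=1.0))
    assert clf.support_vectors.shape[0] == 2
    np.testing.assert_array_equal(predict_instances(clf, X), y)


def test_xor_is_separable_with_rbf():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    clf = train_svm(X, y, SVMParams(C=100.0, g=1.0))
    np.testing.assert_array_equal(clf.predict(X), y)


def test_duplicated_rows_leave_decision_function_unchanged():
    X, y = blobs(seed=3)
    params = SVMParams(C=10.0, g=0.5)
    clf1 = train_svm(X, y, params)
    clf2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), params)
    probes = np.random.default_rng(0).normal(2, 2, size=(50, 2))
    np.testing.assert_allclose(
        clf1.decision_values(probes), clf2.decision_values(probes), atol=1e-6
    )


def test_decision_function_recomputes_from_dual_representation():
    """Recompute sum_i w_i* y_i K(x_i, x) + b* from the stored support
    vectors and compare with the solver's own decision values."""
    X, y = blobs(sep=2.5, seed=7)
    clf = train_svm(X, y, SVMParams(C=5.0, g=0.8))
    probes = np.random.default_rng(1).normal(1, 2, size=(100, 2))
    Z = clf.transform(probes)
    sv = clf.support_vectors
    manual = np.array(
        [
            float(
                np.sum(
                    clf.signed_dual_weights
                    * np.exp(-clf.params.g * np.sum((sv - z) ** 2, axis=1))
                )
                + clf.bias
            )
            for z in Z
        ]
    )
    np.testing.assert_allclose(manual, clf.decision_values(probes), atol=1e-10)
    preds = predict_instances(clf, probes)
    np.testing.assert_array_equal(preds, np.where(manual >= 0, 1, -1))


def test_dual_weights_respect_box_constraint():
    X, y = blobs(sep=1.0, noise=1.0, seed=5)  # overlapping -> bounded SVs exist
    C = 3.0
    clf = train_svm(X, y, SVMParams(C=C, g=0.5))
    w = np.abs(clf.signed_dual_weights)
    assert (w > 0).all()
    assert (w <= C + 1e-9).all()


def test_tie_rule_maps_zero_decision_to_positive():
    class ZeroDecision:
        n_features = 2

        def decision_values(self, X):
            return np.zeros(len(X))

        predict = lambda self, X: np.where(self.decision_values(X) >= 0, 1, -1)

    preds = ZeroDecision().predict(np.zeros((5, 2)))
    assert (preds == 1).all()


def test_train_errors():
    with pytest.raises(ConfigurationError):
        train_svm(np.zeros((3, 2)), [1, 1, 1], SVMParams(C=1, g=1))
    with pytest.raises(ParameterError):
        SVMParams(C=0.0, g=1.0)
    X, y = blobs()
    clf = train_svm(X, y, SVMParams(C=1, g=1))
    with pytest.raises(ParameterError):
        clf.decision_values(np.zeros((4, 3)))  # wrong feature dimension


def test_pso_trace_nondecreasing_and_deterministic():
    X, y = blobs(n_per_class=12, seed=2)
    cfg = PSOConfig(swarm_size=5, iterations=6, fitness_folds=2, seed=9)
    p1, t1 = pso_optimize(X, y, cfg)
    p2, t2 = pso_optimize(X, y, cfg)
    assert t1 == t2
    assert (p1.C, p1.g) == (p2.C, p2.g)
    assert all(b >= a for a, b in zip(t1, t1[1:]))


def test_pso_reaches_perfect_fitness_on_separable_data():
    for seed in (0, 1, 2):
        X, y = blobs(n_per_class=15, sep=6.0, noise=0.4, seed=seed)
        cfg = PSOConfig(swarm_size=8, iterations=10, fitness_folds=3, seed=seed)
        _, trace = pso_optimize(X, y, cfg)
        assert trace[-1] == pytest.approx(1.0)


def quadratic_ridge(c_opt=3.0, g_opt=2.0):
    """Unimodal synthetic fitness with optimum at (c_opt, g_opt)."""

    def fitness(C, g):
        return 1.0 - 0.01 * (C - c_opt) ** 2 - 0.02 * (g - g_opt) ** 2

    return fitness


def test_local_optimize_fixed_point_and_no_degradation():
    fit = quadratic_ridge()
    start = SVMParams(C=3.0, g=2.0)
    out = local_optimize(start, config=LOConfig(), fitness=fit)
    assert (out.C, out.g) == (start.C, start.g)
    worse_start = SVMParams(C=2.4, g=3.1)
    out2 = local_optimize(worse_start, config=LOConfig(), fitness=fit)
    assert fit(out2.C, out2.g) >= fit(worse_start.C, worse_start.g)


def test_local_optimize_matches_exhaustive_grid_oracle():
    """On a unimodal ridge the coordinate search lands on the same grid point
    as a brute-force 2-D sweep of the identical grids."""
    fit = quadratic_ridge(c_opt=3.12, g_opt=1.57)
    start = SVMParams(C=2.8, g=2.3)
    cfg = LOConfig(c_step=0.05, g_step=0.05, c_halfwidth=1.0, g_halfwidth=1.0)
    out = local_optimize(start, config=cfg, fitness=fit)

    c_grid = [start.C + i * cfg.c_step for i in range(-20, 21)]
    g_grid = [start.g + i * cfg.g_step for i in range(-20, 21)]
    best = max(
        ((fit(c, g), -c, -g, c, g) for c in c_grid for g in g_grid),
    )
    assert out.C == pytest.approx(best[3], abs=cfg.c_step + 1e-9)
    assert out.g == pytest.approx(best[4], abs=cfg.g_step + 1e-9)


def test_local_search_tie_break_prefers_smaller_values():
    out = local_optimize(
        SVMParams(C=5.0, g=5.0),
        config=LOConfig(c_step=1.0, g_step=1.0, c_halfwidth=2.0, g_halfwidth=2.0),
        fitness=lambda C, g: 1.0,  # flat: everything ties
    )
    assert out.C == pytest.approx(3.0)
    assert out.g == pytest.approx(3.0)


def test_combined_tuning_never_degrades_pso_fitness():
    X, y = blobs(n_per_class=10, sep=2.0, noise=1.2, seed=4)
    pso_cfg = PSOConfig(swarm_size=4, iterations=4, fitness_folds=2, seed=1)
    lo_cfg = LOConfig(c_step=0.5, g_step=0.5, c_halfwidth=1.0, g_halfwidth=1.0)
    fitness = make_cv_fitness(X, y, 2, 1)
    pso_params, trace = pso_optimize(X, y, pso_cfg, fitness=fitness)
    final, report = tune_svm_params(X, y, pso_cfg, lo_cfg)
    assert report["lo"]["fitness"] >= trace[-1]
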