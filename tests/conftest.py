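import numpy as np
import pytest

from lesionmil.bags import Bag, Instance
from lesionmil.svm_tuning import LOConfig, PSOConfig


@pytest.fixture
def fast_pso():
    """Small PSO budget for unit tests (the tuning contract is budget-free)."""
    return PSOConfig(swarm_size=4, iterations=4, fitness_folds=2, seed=0)


@pytest.fixture
def fast_lo():
    return LOConfig(c_step=0.5, g_step=0.5, c_halfwidth=1.0, g_halfwidth=1.0)


def feature_bag(bag_id, label, features, a_j=None):
    """Bag with injected feature vectors (blocks are 1x1 placeholders)."""
    bag = Bag(bag_id=bag_id, label=label, block_length=1.0)
    for j, f in enumerate(np.atleast_2d(features)):
        bag.instances.append(
            Instance(
                block=np.zeros((1, 1), dtype=np.uint8),
                grid_row=j,
                grid_col=0,
                origin_bag_id=bag_id,
                label=label,
                features=np.asarray(f, dtype=float),
            )
        )
    return bag


def separable_feature_bags(n_pos=6, n_neg=8, n_inst=9, sep=8.0, noise=0.3, seed=0):
    """Positive bags with instances shifted by ``sep`` in the second feature;
    cleanly separable at instance level when sep >> noise.  The first feature
    mimics an ASM mean and stays inside (0, 1) so the background filter never
    fires on these synthetic instances."""
    rng = np.random.default_rng(seed)
    bags = []
    for i in range(n_pos):
        f = np.column_stack(
            [rng.uniform(0.2, 0.8, n_inst), rng.normal(sep, noise, n_inst)]
        )
        bags.append(feature_bag(f"pos{i}", 1, f))
    for i in range(n_neg):
        f = np.column_stack(
            [rng.uniform(0.2, 0.8, n_inst), rng.normal(0, noise, n_inst)]
        )
        bags.append(feature_bag(f"neg{i}", -1, f))
    return bags
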