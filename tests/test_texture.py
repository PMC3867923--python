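"""GLCM computation and statistics against independent oracles."""

import math

import numpy as np
import pytest
from skimage.feature import graycomatrix

from lesionmil.errors import ParameterError, StateError
from lesionmil.texture import (
    DIRECTIONS,
    GLCMConfig,
    GLCMMatrix,
    compute_glcm,
    feature_names,
    glcm_stats,
    instance_features,
    quantize_levels,
)


def brute_force_glcm(block, d, angle, levels):
    """Literal pair enumeration with symmetric accumulation."""
    q = quantize_levels(block, levels)
    dr, dc = DIRECTIONS[angle]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def brute_force_stats(P, log_base=10.0):
    """Direct summation of the four statistics over all cells."""
    G = P.shape[0]
    asm = sum(P[i, j] ** 2 for i in range(G) for j in range(G))
    ent = -sum(
        P[i, j] * math.log(P[i, j], log_base)
        for i in range(G)
        for j in range(G)
        if P[i, j] > 0
    )
    con = sum((i - j) ** 2 * P[i, j] for i in range(G) for j in range(G))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = sum(i * px[i] for i in range(G))
    uy = sum(j * py[j] for j in range(G))
    sx = math.sqrt(sum((i - ux) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j] for j in range(G)))
    if sx * sy > 0:
        cor = (
            sum(i * j * P[i, j] for i in range(G) for j in range(G)) - ux * uy
        ) / (sx * sy)
    else:
        cor = 0.0
    return asm, ent, con, cor


@pytest.mark.parametrize("levels", [2, 3, 4])
@pytest.mark.parametrize("angle", [0, 45, 90, 135])
def test_glcm_matches_bruteforce_on_small_blocks(levels, angle):
    rng = np.random.default_rng(levels * 100 + angle)
    for size in [(2, 2), (3, 5), (4, 4), (8, 8), (8, 5)]:
        block = rng.integers(0, 256, size=size).astype(np.uint8)
        for d in (1, 2):
            if d >= min(size):
                continue
            g = compute_glcm(block, d, angle, levels)
            expected = brute_force_glcm(block, d, angle, levels)
            np.testing.assert_allclose(g.P, expected, atol=1e-12)
            np.testing.assert_allclose(
                glcm_stats(g), brute_force_stats(g.P), atol=1e-12
            )


@pytest.mark.parametrize(
    "angle,sk_angle,sk_scale",
    [
        (0, 0.0, 1.0),
        (45, 3 * math.pi / 4, math.sqrt(2)),
        (90, math.pi / 2, 1.0),
        (135, math.pi / 4, math.sqrt(2)),
    ],
)
def test_glcm_matches_skimage(angle, sk_angle, sk_scale):
    """Independent library cross-check (diagonal offsets step d per axis, so
    the equivalent skimage distance is d*sqrt(2))."""
    rng = np.random.default_rng(9)
    block = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    levels = 8
    q = quantize_levels(block, levels).astype(np.uint8)
    for d in (1, 2):
        mine = compute_glcm(block, d, angle, levels).P
        theirs = graycomatrix(
            q, [d * sk_scale], [sk_angle], levels=levels, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(mine, theirs, atol=1e-12)


def test_constant_block_identities_all_offsets():
    block = np.full((12, 12), 77, dtype=np.uint8)
    for d in (1, 2):
        for angle in (0, 45, 90, 135):
            g = compute_glcm(block, d, angle, levels=8)
            assert np.count_nonzero(g.P) == 1
            asm, ent, con, _ = glcm_stats(g)
            assert asm == 1.0
            assert ent == 0.0
            assert con == 0.0


def test_checkerboard_derived_values():
    """Levels {0, G-1} alternating: all d=1 horizontal pairs straddle the two
    extreme bins, so the mass sits on the two corner cells at 0.5 each."""
    board = (np.indices((4, 4)).sum(axis=0) % 2 * 255).astype(np.uint8)
    g = compute_glcm(board, 1, 0, levels=8)
    corner = np.zeros((8, 8))
    corner[0, 7] = corner[7, 0] = 0.5
    np.testing.assert_allclose(g.P, corner, atol=1e-12)
    asm, ent, con, cor = glcm_stats(g)
    assert asm == pytest.approx(0.5, abs=1e-12)
    assert con == pytest.approx(49.0, abs=1e-12)
    assert ent == pytest.approx(-2 * 0.5 * math.log10(0.5), abs=1e-12)


def test_normalization_and_symmetry_invariants():
    rng = np.random.default_rng(3)
    for _ in range(10):
        block = rng.integers(0, 256, size=(9, 7)).astype(np.uint8)
        g = compute_glcm(block, 1, 45, levels=16)
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.P, g.P.T, atol=1e-15)
        asm, ent, con, cor = glcm_stats(g)
        assert 0 < asm <= 1
        assert ent >= 0
        assert abs(cor) <= 1 + 1e-9
        # ASM = 1 iff ENT = 0 iff exactly one nonzero cell
        assert (asm == 1.0) == (ent == 0.0) == (np.count_nonzero(g.P) == 1)


def test_glcm_parameter_errors():
    block = np.zeros((4, 4), dtype=np.uint8)
    with pytest.raises(ParameterError):
        compute_glcm(block, 4, 0, levels=8)  # d >= block side
    with pytest.raises(ParameterError):
        compute_glcm(block, 1, 30, levels=8)  # unknown direction
    bad = GLCMMatrix(P=np.full((2, 2), 0.3), levels=2, distance=1, angle=0)
    with pytest.raises(StateError):
        glcm_stats(bad)  # unnormalized


def test_feature_vector_layout_and_constant_block():
    cfg = GLCMConfig()
    names = feature_names(cfg)
    assert len(names) == cfg.n_features == 16
    assert names[0] == "asm_mean_d1"
    vec = instance_features(np.full((10, 10), 42, dtype=np.uint8), cfg)
    assert vec.shape == (16,)
    named = dict(zip(names, vec))
    for d in (1, 2):
        assert named[f"asm_mean_d{d}"] == 1.0
        assert named[f"asm_var_d{d}"] == 0.0
        assert named[f"ent_mean_d{d}"] == 0.0
        assert named[f"con_mean_d{d}"] == 0.0
    pooled = GLCMConfig(pool_distances=True)
    assert len(feature_names(pooled)) == pooled.n_features == 8
    assert instance_features(np.full((10, 10), 42, dtype=np.uint8), pooled).shape == (8,)


def test_variance_entries_nonnegative_and_rotation_invariance():
    """A 90-degree rotation permutes the four directional matrices, so the
    per-distance mean and variance entries are unchanged."""
    rng = np.random.default_rng(11)
    block = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    cfg = GLCMConfig(levels=8)
    v1 = instance_features(block, cfg)
    v2 = instance_features(np.rot90(block).copy(), cfg)
    names = feature_names(cfg)
    var_idx = [i for i, n in enumerate(names) if "_var_" in n]
    assert (v1[var_idx] >= 0).all()
    np.testing.assert_allclose(v1, v2, atol=1e-10)
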