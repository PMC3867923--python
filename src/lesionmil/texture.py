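"""Gray-level co-occurrence matrix (GLCM) texture features.

A GLCM tabulates how often two gray levels co-occur at a fixed pixel offset
(distance ``d``, direction ``theta``).  Four classical Haralick-style
statistics are derived from each normalized matrix:

* **ASM** (angular second moment) -- uniformity of the gray-level
  distribution; exactly 1 for a single-level block.
* **ENT** (entropy) -- texture complexity, ``-sum p * log10 p``.
* **CON** (contrast) -- local intensity variation, ``sum (i-j)^2 * p``.
* **COR** (correlation) -- linear dependence of co-occurring levels, using
  the standard marginal means/standard deviations of the matrix.

Per instance (image block) the matrices for 4 directions x 2 distances are
computed and, per distance, each statistic's mean and population variance
across the 4 directions is emitted, giving a 16-dimensional feature vector
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StateError

__all__ = [
    "GLCMConfig",
    "GLCMMatrix",
    "DIRECTIONS",
    "quantize_levels",
    "compute_glcm",
    "glcm_stats",
    "instance_features",
    "feature_names",
]

#: direction -> (row, col) unit offset; angles follow the convention that
#: 0 deg is the horizontal neighbor and angles increase counter-clockwise
#: (45 deg = up-right).  With symmetric accumulation the sign of the offset
#: does not matter.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class GLCMConfig:
    """Feature-extraction settings for one instance.

    ``levels`` is the number of equal-width gray bins on [0, 255]; 64 keeps
    enough texture resolution for ~100x100 blocks without starving the
    co-occurrence counts.  ``log_base`` controls the entropy logarithm
    (base 10 by default).  ``pool_distances=True`` collapses the two
    distances into one mean/variance over all 8 matrices (8-dim vector).
    """

    distances: tuple[int, ...] = (1, 2)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 64
    log_base: float = 10.0
    pool_distances: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ParameterError(f"levels must be >= 2, got {self.levels}")
        for a in self.angles:
            if a not in DIRECTIONS:
                raise ParameterError(f"angles must be in {sorted(DIRECTIONS)}, got {a}")
        if any(d < 1 for d in self.distances):
            raise ParameterError(f"distances must be >= 1, got {self.distances}")
        if self.log_base <= 1:
            raise ParameterError(f"log_base must be > 1, got {self.log_base}")

    @property
    def n_features(self) -> int:
        n_stats = 4 * 2  # {ASM, ENT, CON, COR} x {mean, var}
        return n_stats if self.pool_distances else n_stats * len(self.distances)


@dataclass
class GLCMMatrix:
    """Normalized co-occurrence probability table for one (distance, direction)."""

    P: np.ndarray
    levels: int
    distance: int
    angle: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.levels, self.levels):
            raise ParameterError(
                f"P must be {self.levels}x{self.levels}, got {self.P.shape}"
            )


def quantize_levels(block: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit intensities onto ``levels`` equal-width bins of [0, 255]."""
    b = np.asarray(block)
    if b.ndim != 2:
        raise ParameterError(f"block must be 2-D, got shape {b.shape}")
    if b.size == 0:
        raise ParameterError("block is empty")
    if b.min() < 0 or b.max() > 255:
        raise ParameterError("block intensities must lie in [0, 255]")
    q = (b.astype(np.int64) * levels) // 256
    return np.minimum(q, levels - 1)


def compute_glcm(
    block: np.ndarray, distance: int, angle: int, levels: int = 64
) -> GLCMMatrix:
    """Normalized, symmetrically accumulated GLCM of one block.

    Every in-bounds pixel pair separated by the (distance, angle) offset is
    counted in both orderings, then the table is normalized to sum 1.
    """
    if angle not in DIRECTIONS:
        raise ParameterError(f"angle must be in {sorted(DIRECTIONS)}, got {angle}")
    q = quantize_levels(block, levels)
    h, w = q.shape
    if distance < 1 or distance >= min(h, w):
        raise ParameterError(
            f"distance must satisfy 1 <= d < min(block side)={min(h, w)}, got {distance}"
        )
    dr, dc = DIRECTIONS[angle]
    dr *= distance
    dc *= distance
    src = q[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    dst = q[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
    counts = np.bincount(
        (src.ravel() * levels + dst.ravel()), minlength=levels * levels
    ).reshape(levels, levels)
    counts = counts + counts.T  # both pair orderings
    total = counts.sum()
    if total == 0:
        raise ParameterError("no valid pixel pairs for the requested offset")
    return GLCMMatrix(P=counts / total, levels=levels, distance=distance, angle=angle)


def glcm_stats(
    glcm: GLCMMatrix, log_base: float = 10.0
) -> tuple[float, float, float, float]:
    """(ASM, ENT, CON, COR) of a normalized GLCM.

    Correlation uses the standard marginal definitions
    ``u_x = sum_i i * p_x(i)`` and ``sigma_x^2 = sum_i (i - u_x)^2 * p_x(i)``
    over bin indices 0..G-1, and is defined as 0 when either marginal spread
    vanishes (single-level block).
    """
    P = glcm.P
    if abs(P.sum() - 1.0) > 1e-8:
        raise StateError("GLCM is not normalized; entries must sum to 1")
    if (P < 0).any():
        raise StateError("GLCM has negative entries")
    idx = np.arange(glcm.levels, dtype=float)
    asm = float((P * P).sum())
    nz = P[P > 0]
    ent = float(-(nz * (np.log(nz) / np.log(log_base))).sum())
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    con = float((diff2 * P).sum())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(idx @ px)
    uy = float(idx @ py)
    sx = float(np.sqrt(((idx - ux) ** 2) @ px))
    sy = float(np.sqrt(((idx - uy) ** 2) @ py))
    if sx * sy > 0:
        cor = float(((np.outer(idx, idx) * P).sum() - ux * uy) / (sx * sy))
    else:
        cor = 0.0
    return asm, ent, con, cor


_STAT_NAMES = ("asm", "ent", "con", "cor")


def feature_names(config: GLCMConfig | None = None) -> list[str]:
    """Ordered names of the entries produced by :func:`instance_features`."""
    config = config or GLCMConfig()
    names: list[str] = []
    if config.pool_distances:
        for agg in ("mean", "var"):
            names.extend(f"{s}_{agg}" for s in _STAT_NAMES)
        return names
    for d in config.distances:
        for agg in ("mean", "var"):
            names.extend(f"{s}_{agg}_d{d}" for s in _STAT_NAMES)
    return names


def instance_features(block: np.ndarray, config: GLCMConfig | None = None) -> np.ndarray:
    """Feature vector of one block: per distance, the mean and population
    variance of each statistic across the configured directions."""
    config = config or GLCMConfig()
    per_distance: list[np.ndarray] = []
    for d in config.distances:
        stats = np.array(
            [
                glcm_stats(
                    compute_glcm(block, d, a, config.levels), config.log_base
                )
                for a in config.angles
            ]
        )  # (n_angles, 4)
        per_distance.append(stats)
    out: list[float] = []
    if config.pool_distances:
        stats = np.vstack(per_distance)
        out.extend(stats.mean(axis=0))
        out.extend(stats.var(axis=0))
    else:
        for stats in per_distance:
            out.extend(stats.mean(axis=0))
            out.extend(stats.var(axis=0))
    vec = np.asarray(out, dtype=float)
    if not np.isfinite(vec).all():
        raise StateError("non-finite texture feature encountered")
    return vec
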