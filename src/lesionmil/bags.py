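"""Bag/instance data model and equal-block instance extraction.

One preprocessed grayscale image is a *bag*; the square blocks tiled from it
are its *instances*.  Under multi-instance supervision a bag is positive iff
it contains at least one lesion-class instance, so instance labels are not
observed directly -- they are inherited from the bag label during training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, StateError
from .texture import GLCMConfig, instance_features

__all__ = [
    "Instance",
    "Bag",
    "tile_boundaries",
    "extract_instances",
    "label_instances",
    "compute_bag_features",
    "save_bag_json",
    "load_bag_json",
]

UNLABELED = 0


@dataclass
class Instance:
    """One square block of a bag.

    ``a_j`` is the selection flag used during classifier construction: it
    defaults to 0 and is set to 1 only when the instance is retained from a
    positive bag as a key ("excellent") instance.
    """

    block: np.ndarray
    grid_row: int
    grid_col: int
    origin_bag_id: str
    label: int = UNLABELED
    a_j: int = 0
    features: np.ndarray | None = None


@dataclass
class Bag:
    """An ordered collection of instances tiled from one image."""

    bag_id: str
    label: int = UNLABELED
    instances: list[Instance] = field(default_factory=list)
    block_length: float = 0.0
    removed_background: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_i(self) -> int:
        return len(self.instances)

    def feature_matrix(self) -> np.ndarray:
        if any(inst.features is None for inst in self.instances):
            raise StateError(f"bag {self.bag_id}: instance features not computed")
        return np.vstack([inst.features for inst in self.instances])


def tile_boundaries(side: int, block_length: float) -> list[int]:
    """Pixel boundaries of the equal partition of ``side`` pixels into
    ``k = round(side / block_length)`` contiguous runs.

    Fractional block lengths are supported (e.g. 169.5 on a 339-pixel side
    gives runs of 170 and 169 pixels); every pixel is covered exactly once.
    """
    if not (1 <= block_length <= side):
        raise ParameterError(
            f"block_length must lie in [1, {side}], got {block_length}"
        )
    k = max(1, int(math.floor(side / block_length + 0.5)))
    return [int(math.floor(i * side / k + 0.5)) for i in range(k + 1)]


def extract_instances(
    img: np.ndarray,
    block_length: float,
    bag_id: str = "bag",
    label: int = UNLABELED,
) -> Bag:
    """Tile an image into a bag of equal blocks, ordered row-major."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ParameterError(f"image must be 2-D, got shape {img.shape}")
    rows = tile_boundaries(img.shape[0], block_length)
    cols = tile_boundaries(img.shape[1], block_length)
    bag = Bag(bag_id=bag_id, label=label, block_length=float(block_length))
    for gr in range(len(rows) - 1):
        for gc in range(len(cols) - 1):
            block = img[rows[gr] : rows[gr + 1], cols[gc] : cols[gc + 1]].copy()
            bag.instances.append(
                Instance(block=block, grid_row=gr, grid_col=gc, origin_bag_id=bag_id)
            )
    return bag


def label_instances(bag: Bag) -> Bag:
    """Propagate the bag label to every instance (in place).

    Positive-bag instances are marked +1, negative-bag instances -1; this is
    the weak labeling that the later instance-selection stage refines.
    """
    if bag.label not in (1, -1):
        raise StateError(f"bag {bag.bag_id} is unlabeled; cannot label instances")
    for inst in bag.instances:
        inst.label = bag.label
    return bag


def compute_bag_features(bag: Bag, config: GLCMConfig | None = None) -> Bag:
    """Attach the GLCM feature vector to every instance (in place)."""
    config = config or GLCMConfig()
    for inst in bag.instances:
        inst.features = instance_features(inst.block, config)
    return bag


def save_bag_json(bag: Bag, path: str | Path) -> Path:
    """Write a JSON sidecar describing the bag (no pixel data)."""
    path = Path(path)
    payload = {
        "bag_id": bag.bag_id,
        "label": bag.label,
        "block_length": bag.block_length,
        "removed_background": [list(rc) for rc in bag.removed_background],
        "instances": [
            {
                "grid_row": inst.grid_row,
                "grid_col": inst.grid_col,
                "label": inst.label,
                "a_j": inst.a_j,
            }
            for inst in bag.instances
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_bag_json(path: str | Path) -> dict:
    """Read a bag sidecar written by :func:`save_bag_json`."""
    return json.loads(Path(path).read_text())
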