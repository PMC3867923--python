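"""Synthetic liver-CT-like phantom images with ground-truth lesion masks.

The generator emulates the study conditions the classifier is meant for:
512x512 8-bit frames containing a single elliptical "organ" on a uniform
zero background, with four tissue classes:

* ``normal``    -- smooth correlated parenchyma texture, no focal lesion;
* ``cancer``    -- one or more irregular focal lesions (union of jittered
                   disks) with an intensity offset and distinct texture;
* ``cirrhosis`` -- globally rougher parenchyma (larger intensity spread,
                   shorter correlation length), no focal lesion;
* ``cyst``      -- a single round, internally near-homogeneous, sharply
                   bounded lesion.

Under multi-instance supervision the bag label is +1 iff the class is
``cancer``.  The parenchyma texture is white Gaussian noise smoothed with a
Gaussian kernel (correlation length in pixels), scaled to the requested
mean/spread and quantized to 8 bits; the GLCM statistics respond smoothly
to both knobs.  Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .preprocessing import write_image

__all__ = [
    "CLASS_NAMES",
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "read_manifest",
]

CLASS_NAMES = ("normal", "cancer", "cirrhosis", "cyst")

#: per-class parameter adjustments; cirrhosis is rough-textured with no
#: focal lesion, cysts are single homogeneous dark disks.
_CLASS_DEFAULTS: dict[str, dict] = {
    "normal": {},
    "cancer": {},
    "cirrhosis": {"base_std": 38.0, "texture_correlation_length": 1.8},
    "cyst": {
        "lesion_count_range": (1, 1),
        "lesion_radius_range": (45.0, 70.0),
        "lesion_contrast": -90.0,
        "lesion_texture_std": 1.5,
    },
}


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of one phantom image.

    Intensities are 8-bit gray values; lengths are pixels at the generated
    resolution (512 by default, before any downstream resizing).  The
    lesion fields are ignored for the ``normal`` and ``cirrhosis`` classes.
    """

    image_side: int = 512
    organ_fraction: float = 0.45
    base_mean: float = 120.0
    base_std: float = 20.0
    texture_correlation_length: float = 6.0
    lesion_count_range: tuple[int, int] = (2, 4)
    lesion_radius_range: tuple[float, float] = (45.0, 70.0)
    lesion_contrast: float = -60.0
    lesion_texture_std: float = 12.0
    class_name: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 64:
            raise ParameterError(f"image_side must be >= 64, got {self.image_side}")
        if not (0 < self.organ_fraction < 1):
            raise ParameterError(
                f"organ_fraction must lie in (0, 1), got {self.organ_fraction}"
            )
        if not (0 <= self.base_mean <= 255):
            raise ParameterError(f"base_mean must lie in [0, 255], got {self.base_mean}")
        if self.base_std < 0:
            raise ParameterError(f"base_std must be >= 0, got {self.base_std}")
        if self.texture_correlation_length <= 0:
            raise ParameterError(
                "texture_correlation_length must be > 0, got "
                f"{self.texture_correlation_length}"
            )
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi):
            raise ParameterError(
                f"lesion_count_range must be 0 <= min <= max, got {self.lesion_count_range}"
            )
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ParameterError(
                f"lesion_radius_range must be 0 < min <= max, got {self.lesion_radius_range}"
            )
        if self.lesion_texture_std < 0:
            raise ParameterError(
                f"lesion_texture_std must be >= 0, got {self.lesion_texture_std}"
            )
        if self.class_name not in CLASS_NAMES:
            raise ParameterError(
                f"class_name must be one of {CLASS_NAMES}, got {self.class_name!r}"
            )
        if self.class_name == "cancer" and lo < 1:
            raise ParameterError(
                "lesion_count_range min must be >= 1 for the cancer class"
            )

    @classmethod
    def for_class(cls, class_name: str, seed: int = 0, **overrides) -> "PhantomConfig":
        """Class-appropriate defaults (rough texture for cirrhosis, etc.)."""
        if class_name not in CLASS_NAMES:
            raise ParameterError(
                f"class_name must be one of {CLASS_NAMES}, got {class_name!r}"
            )
        kwargs = dict(_CLASS_DEFAULTS[class_name])
        kwargs.update(overrides)
        return cls(class_name=class_name, seed=seed, **kwargs)


@dataclass
class PhantomSample:
    image: np.ndarray
    bag_label: int
    class_name: str
    lesion_mask: np.ndarray
    seed_used: int


def _correlated_field(rng, side: int, corr_len: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with the given smoothing scale."""
    f = gaussian_filter(rng.standard_normal((side, side)), sigma=corr_len, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _irregular_blob(rng, center: tuple[float, float], radius: float,
                    shape: tuple[int, int]) -> np.ndarray:
    """Union of 3-7 jittered overlapping disks around ``center``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    n_sub = int(rng.integers(3, 8))
    for _ in range(n_sub):
        jr = center[0] + rng.uniform(-0.5, 0.5) * radius
        jc = center[1] + rng.uniform(-0.5, 0.5) * radius
        sub_r = rng.uniform(0.45, 0.75) * radius
        mask |= (rr - jr) ** 2 + (cc - jc) ** 2 <= sub_r**2
    return mask


def _disk(center: tuple[float, float], radius: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Render one phantom; deterministic in (config, config.seed)."""
    rng = default_rng(config.seed)
    side = config.image_side
    shape = (side, side)

    # organ geometry: a mildly eccentric, slightly rotated ellipse kept
    # strictly inside the frame
    aspect = rng.uniform(1.1, 1.4)
    b_ax = float(np.sqrt(config.organ_fraction * side * side / (np.pi * aspect)))
    a_ax = aspect * b_ax
    max_ax = 0.48 * side
    if a_ax > max_ax:  # preserve the area cap while fitting in the frame
        a_ax = max_ax
        b_ax = config.organ_fraction * side * side / (np.pi * a_ax)
    margin = side / 2 - max(a_ax, b_ax)
    jitter = min(0.03 * side, max(margin - 2, 0))
    cy = side / 2 + rng.uniform(-jitter, jitter)
    cx = side / 2 + rng.uniform(-jitter, jitter)
    phi = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[:side, :side]
    u = (cc - cx) * np.cos(phi) + (rr - cy) * np.sin(phi)
    v = -(cc - cx) * np.sin(phi) + (rr - cy) * np.cos(phi)
    organ = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0

    parenchyma = _correlated_field(rng, side, config.texture_correlation_length)
    lesion_field = _correlated_field(
        rng, side, max(0.8 * config.texture_correlation_length, 1.0)
    )

    img = np.zeros(shape, dtype=float)
    img[organ] = config.base_mean + config.base_std * parenchyma[organ]

    mask = np.zeros(shape, dtype=np.uint8)
    if config.class_name in ("cancer", "cyst"):
        organ_rows, organ_cols = np.nonzero(organ)
        lo, hi = config.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(n_lesions):
            pick = int(rng.integers(organ_rows.size))
            center = (float(organ_rows[pick]), float(organ_cols[pick]))
            radius = rng.uniform(*config.lesion_radius_range)
            if config.class_name == "cancer":
                blob = _irregular_blob(rng, center, radius, shape)
            else:
                blob = _disk(center, radius, shape)
            blob &= organ
            img[blob] = (
                config.base_mean
                + config.lesion_contrast
                + config.lesion_texture_std * lesion_field[blob]
            )
            mask[blob] = 1

    img[organ] = np.clip(img[organ], 1, 255)  # keep background value 0 unique
    image = np.floor(img + 0.5).astype(np.uint8)
    bag_label = 1 if config.class_name == "cancer" else -1
    return PhantomSample(
        image=image,
        bag_label=bag_label,
        class_name=config.class_name,
        lesion_mask=mask,
        seed_used=config.seed,
    )


def generate_dataset(
    per_class_counts: dict[str, int],
    config_overrides: dict[str, dict] | None = None,
    master_seed: int = 0,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate a labeled dataset with a (path, class, label, split) manifest.

    Per-sample seeds are derived from ``master_seed`` via a seed sequence, so
    the same master seed reproduces the dataset bit for bit.  Each class is
    split 50/50 into train/test (train gets the floor on odd counts) with a
    seeded shuffle.
    """
    config_overrides = config_overrides or {}
    for name, count in per_class_counts.items():
        if name not in CLASS_NAMES:
            raise ParameterError(f"unknown class {name!r}")
        if count < 0:
            raise ParameterError(f"count for {name!r} must be >= 0, got {count}")
    ss = SeedSequence(master_seed)
    total = sum(per_class_counts.values())
    children = ss.spawn(total + 1)
    split_rng = default_rng(children[0])
    samples: list[PhantomSample] = []
    rows: list[dict] = []
    child_idx = 1
    for name in sorted(per_class_counts):
        count = per_class_counts[name]
        n_train = count // 2
        splits = np.array(["train"] * n_train + ["test"] * (count - n_train))
        splits = splits[split_rng.permutation(count)]
        for i in range(count):
            seed_used = int(children[child_idx].generate_state(1)[0] % (2**31))
            child_idx += 1
            cfg = PhantomConfig.for_class(
                name, seed=seed_used, **config_overrides.get(name, {})
            )
            sample = generate_phantom(cfg)
            samples.append(sample)
            rows.append(
                {
                    "path": f"{name}_{i:04d}.png",
                    "class": name,
                    "label": sample.bag_label,
                    "split": splits[i],
                }
            )
    manifest = pd.DataFrame(rows, columns=["path", "class", "label", "split"])
    return samples, manifest


def write_dataset(
    samples: list[PhantomSample],
    directory: str | Path,
    manifest: pd.DataFrame | None = None,
) -> Path:
    """Write images (PNG), lesion masks (``*_mask.png``, 0/255) and the CSV
    manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        per_class: dict[str, int] = {}
        rows = []
        for s in samples:
            i = per_class.get(s.class_name, 0)
            per_class[s.class_name] = i + 1
            rows.append(
                {
                    "path": f"{s.class_name}_{i:04d}.png",
                    "class": s.class_name,
                    "label": s.bag_label,
                    "split": "train",
                }
            )
        manifest = pd.DataFrame(rows, columns=["path", "class", "label", "split"])
    if len(manifest) != len(samples):
        raise ParameterError(
            f"manifest has {len(manifest)} rows for {len(samples)} samples"
        )
    for sample, path in zip(samples, manifest["path"]):
        img_path = directory / path
        try:
            write_image(sample.image, img_path)
            write_image(
                sample.lesion_mask * 255, img_path.with_name(img_path.stem + "_mask.png")
            )
        except OSError as exc:
            raise IOError(f"failed to write {img_path}: {exc}") from exc
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Load a dataset manifest, validating the expected columns."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = {"path", "class", "label", "split"} - set(df.columns)
    if missing:
        raise IOError(f"manifest {manifest_path} lacks columns {sorted(missing)}")
    return df
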