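"""Image reading, size normalization, and histogram equalization.

Incoming images are 8-bit grayscale (BMP or PNG), one image per bag.  The
pipeline resizes every frame to a common square side (default 339 px) and
applies global 256-bin histogram equalization to sharpen texture contrast
between tissue classes.  Equalization is a monotone intensity remap, so
pixel rank order is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ParameterError

__all__ = [
    "PreprocessConfig",
    "read_image",
    "write_image",
    "normalize_size",
    "equalize_histogram",
    "preprocess",
]

_RESAMPLE = {
    "nearest": Image.Resampling.NEAREST,
    "bilinear": Image.Resampling.BILINEAR,
}


@dataclass(frozen=True)
class PreprocessConfig:
    target_side: int = 339
    equalize: bool = True
    resize_method: str = "bilinear"

    def __post_init__(self) -> None:
        if self.target_side < 2:
            raise ParameterError(f"target_side must be >= 2, got {self.target_side}")
        if self.resize_method not in _RESAMPLE:
            raise ParameterError(
                f"resize_method must be one of {sorted(_RESAMPLE)}, got {self.resize_method!r}"
            )


def read_image(path: str | Path) -> np.ndarray:
    """Load a BMP/PNG image as a 2-D uint8 array (multi-channel -> luminance)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                im = im.convert("L")
            arr = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise IOError(f"unsupported or corrupt image file: {path}") from exc
    if arr.ndim != 2:
        raise IOError(f"could not interpret {path} as a single-channel image")
    return arr


def write_image(img: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D uint8 array losslessly (format from the file suffix)."""
    path = Path(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ParameterError(f"image must be 2-D, got shape {arr.shape}")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    return path


def normalize_size(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Resize to target_side x target_side (bilinear by default).

    An input already at the target size is returned unchanged.
    """
    config = config or PreprocessConfig()
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 2:
        raise ParameterError(f"image must be 2-D, got shape {arr.shape}")
    t = config.target_side
    if arr.shape == (t, t):
        return arr.copy()
    im = Image.fromarray(arr, mode="L").resize((t, t), _RESAMPLE[config.resize_method])
    return np.asarray(im, dtype=np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global 256-bin histogram equalization via the classic CDF remap.

    The lookup table is ``round(255 * (cdf - cdf_min) / (1 - cdf_min))``, a
    monotone map that keeps the darkest occupied level at 0.  A constant
    image is returned unchanged (degenerate histogram).
    """
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 2:
        raise ParameterError(f"image must be 2-D, got shape {arr.shape}")
    hist = np.bincount(arr.ravel(), minlength=256).astype(float)
    cdf = np.cumsum(hist) / arr.size
    occupied = np.flatnonzero(hist)
    if occupied.size <= 1:
        return arr.copy()
    cdf_min = cdf[occupied[0]]
    lut = np.floor(255.0 * (cdf - cdf_min) / (1.0 - cdf_min) + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[arr]


def preprocess(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Size normalization followed by (optional) histogram equalization."""
    config = config or PreprocessConfig()
    out = normalize_size(img, config)
    if config.equalize:
        out = equalize_histogram(out)
    return out
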