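"""Tissue localisation and fixed-size patch extraction.

Tissue is separated from background by the per-pixel colorization value

    c(r, g, b) = |r - m| + |g - m| + |b - m|,   m = (r + g + b) / 3,

which is zero exactly for grey pixels and positive for coloured (stained)
ones, followed by an adaptive (local-mean) or fixed threshold.  Larger
images are then tiled into non-overlapping square patches and a tile is
kept when its tissue-pixel fraction reaches ``min_tissue_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from skimage.filters import threshold_local

from .errors import InputError
from .models import PatchedImage

__all__ = [
    "ColorizationParams",
    "colorization_value",
    "tissue_mask",
    "extract_patches",
    "PatchCandidate",
    "load_image",
]


@dataclass(frozen=True)
class ColorizationParams:
    """Thresholding configuration for tissue masking.

    ``threshold`` is only used in fixed mode; ``window``/``offset``
    parameterise the local-mean adaptive threshold.
    """

    threshold_mode: str = "adaptive"
    window: int = 51
    offset: float = 0.0
    threshold: float = 0.05
    min_tissue_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("adaptive", "fixed"):
            raise InputError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise InputError("window must be an odd integer >= 3")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise InputError("min_tissue_fraction must lie in [0, 1]")


def colorization_value(image: np.ndarray) -> np.ndarray:
    """Per-pixel colorization value; invariant to channel permutation and
    to adding a common constant to all three channels."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected H x W x 3 image, got shape {image.shape}")
    m = image.mean(axis=2, keepdims=True)
    return np.abs(image - m).sum(axis=2)


def tissue_mask(image: np.ndarray, params: ColorizationParams | None = None) -> np.ndarray:
    """Binary H x W mask: True where the colorization value exceeds the
    (fixed or local-mean adaptive) threshold."""
    params = params or ColorizationParams()
    c = colorization_value(image)
    if params.threshold_mode == "fixed":
        return c > params.threshold
    if params.window > min(c.shape):
        raise InputError(
            f"adaptive window {params.window} exceeds image size {c.shape}"
        )
    # our offset is added to the local mean (skimage subtracts its offset)
    thresh = threshold_local(c, block_size=params.window, offset=-params.offset)
    return c > thresh


class PatchCandidate(NamedTuple):
    image: np.ndarray  # (patch, patch, 3)
    coord: tuple[int, int]  # 0-based (row, col) in the tiling
    tissue_fraction: float


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 256,
    min_tissue_fraction: float = 0.1,
) -> list[PatchCandidate]:
    """Non-overlapping row-major tiling; emit tiles whose tissue fraction
    reaches the minimum.  Edge remainders that do not fill a tile are
    dropped; an empty result is an empty list, not an error."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise InputError("image and mask shapes disagree")
    h, w = mask.shape
    if h < patch_size or w < patch_size:
        raise InputError(
            f"image {h}x{w} holds no full {patch_size}px patch in each dimension"
        )
    out: list[PatchCandidate] = []
    for r in range(h // patch_size):
        for c in range(w // patch_size):
            rs = slice(r * patch_size, (r + 1) * patch_size)
            cs = slice(c * patch_size, (c + 1) * patch_size)
            frac = float(mask[rs, cs].mean())
            if frac >= min_tissue_fraction:
                out.append(PatchCandidate(image[rs, cs], (r, c), frac))
    return out


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image into a float H x W x 3 array in [0, 1]."""
    from PIL import Image as PILImage

    with PILImage.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr
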