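"""Seed-reproducible pseudo-histology generator and analytic toy classifiers.

The generator emulates the colour structure of an H&E-stained slide at
patch granularity: "tumor" patches are purple-dominant, "normal tissue"
patches pink-dominant, and background patches near-grey so their
colorization value (see :mod:`patchexplain.preprocessing`) is near zero.
Ground-truth patch labels are returned alongside the image, which makes
every attribution method and metric testable with no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .models import ClassifierAdapter, LinearPatchScorer, PatchedImage, TinyViT

__all__ = [
    "TUMOR",
    "NORMAL",
    "BACKGROUND",
    "DEFAULT_PALETTE",
    "SyntheticSlideSpec",
    "GroundTruth",
    "generate_pseudo_slide",
    "make_linear_patch_scorer",
    "make_tumor_signal_scorer",
    "make_tiny_vit",
    "export_slide",
]

TUMOR = "tumor"
NORMAL = "normal"
BACKGROUND = "background"

# Purple/pink/grey palette; tumor is also distinctly darker in mean
# intensity than normal tissue, so an intensity-weighted linear model can
# genuinely prefer tumor patches.
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    TUMOR: (0.50, 0.30, 0.60),
    NORMAL: (0.93, 0.72, 0.82),
    BACKGROUND: (0.92, 0.92, 0.92),
}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Layout and texture parameters of one pseudo-slide.

    Patches not listed as tumor or background are "normal tissue"; the
    three index sets must be disjoint.  ``noise_scale`` is the standard
    deviation of per-pixel Gaussian colour noise (clipped to [0, 1]); the
    default is small enough that tissue/background separation by
    colorization value holds with margin.
    """

    grid: tuple[int, int] = (4, 4)
    patch_size: int = 16
    tumor_patches: frozenset[int] = frozenset({0})
    background_patches: frozenset[int] = frozenset()
    palette: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.grid[0] * self.grid[1]
        tumor = frozenset(int(i) for i in self.tumor_patches)
        bg = frozenset(int(i) for i in self.background_patches)
        if tumor & bg:
            raise InputError(f"tumor and background patch sets overlap: {tumor & bg}")
        for s in (tumor, bg):
            if s and (min(s) < 0 or max(s) >= d):
                raise InputError(f"patch index out of range for d={d}")
        for color in self.palette.values():
            if not all(0.0 <= v <= 1.0 for v in color):
                raise InputError("palette colors must lie in [0, 1]")
        object.__setattr__(self, "tumor_patches", tumor)
        object.__setattr__(self, "background_patches", bg)

    @property
    def d(self) -> int:
        return self.grid[0] * self.grid[1]

    def labels(self) -> list[str]:
        return [
            TUMOR
            if i in self.tumor_patches
            else BACKGROUND
            if i in self.background_patches
            else NORMAL
            for i in range(self.d)
        ]


@dataclass(frozen=True)
class GroundTruth:
    """Per-patch labels over {tumor, normal, background}, length d."""

    patch_labels: tuple[str, ...]

    @property
    def d(self) -> int:
        return len(self.patch_labels)

    def indices(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, l in enumerate(self.patch_labels) if l == label], dtype=int
        )


def generate_pseudo_slide(spec: SyntheticSlideSpec) -> tuple[PatchedImage, GroundTruth]:
    """Render the spec into an image; the same seed gives identical arrays."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    p = spec.patch_size
    labels = spec.labels()
    pixels = np.empty((rows * p, cols * p, 3))
    for i, label in enumerate(labels):
        r, c = divmod(i, cols)
        base = np.asarray(spec.palette[label])
        tile = base + rng.normal(0.0, spec.noise_scale, size=(p, p, 3))
        pixels[r * p : (r + 1) * p, c * p : (c + 1) * p, :] = tile
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return PatchedImage(pixels, p), GroundTruth(tuple(labels))


def make_linear_patch_scorer(
    weights: np.ndarray,
    bias: float = 0.0,
    link: str = "identity",
    attention_temperature: float | None = None,
) -> LinearPatchScorer:
    """Analytic scorer: score = sum_i weight_i * mean_intensity(patch i) + bias.

    Under the identity link the induced image game is additive, so the
    exact Shapley value of patch i is its own contribution — the module's
    key closed-form oracle.
    """
    return LinearPatchScorer(weights, bias, link, attention_temperature)


def make_tumor_signal_scorer(
    truth: GroundTruth,
    tumor_weight: float = 3.0,
    normal_weight: float = 0.5,
    bias: float | None = None,
    link: str = "sigmoid",
    attention_temperature: float | None = 0.15,
) -> LinearPatchScorer:
    """An idealised tumor-recognising classifier for planted-signal studies.

    Its true per-patch dependence is known by construction (tumor patches
    carry the large weights), so attribution methods can be scored on how
    well they recover it.  The default bias centres the sigmoid halfway
    between the empty and full coalitions of a default-palette slide.
    """
    w = np.where(
        np.isin(np.arange(truth.d), truth.indices(TUMOR)),
        tumor_weight,
        np.where(np.isin(np.arange(truth.d), truth.indices(NORMAL)), normal_weight, 0.0),
    )
    if bias is None:
        mu = {
            TUMOR: float(np.mean(DEFAULT_PALETTE[TUMOR])),
            NORMAL: float(np.mean(DEFAULT_PALETTE[NORMAL])),
        }
        full = (
            tumor_weight * mu[TUMOR] * len(truth.indices(TUMOR))
            + normal_weight * mu[NORMAL] * len(truth.indices(NORMAL))
        )
        bias = -full / 2.0
    return LinearPatchScorer(w, bias, link, attention_temperature)


def make_tiny_vit(
    layers: int = 2,
    heads: int = 2,
    d: int = 16,
    seed: int = 0,
    patch_size: int = 8,
    embed_dim: int = 16,
    n_classes: int = 2,
) -> TinyViT:
    """Randomly initialised NumPy transformer over a square grid of d patches."""
    side = int(round(np.sqrt(d)))
    if side * side != d:
        raise InputError(f"d={d} is not a perfect square")
    return TinyViT(
        image_size=side * patch_size,
        patch_size=patch_size,
        depth=layers,
        heads=heads,
        embed_dim=embed_dim,
        n_classes=n_classes,
        seed=seed,
    )


def export_slide(
    image: PatchedImage,
    truth: GroundTruth,
    out_dir: str | Path,
    slide_id: str = "slide_0",
) -> Path:
    """Write patches as 8-bit PNGs plus a JSON ground truth and CSV manifest."""
    from PIL import Image as PILImage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = image.grid
    to8 = lambda a: (np.clip(a, 0, 1) * 255).round().astype(np.uint8)
    PILImage.fromarray(to8(image.pixels)).save(out / f"{slide_id}.png")
    lines = ["slide_id,patch_id,row,col,label"]
    patches = image.patch_array()
    for i, label in enumerate(truth.patch_labels):
        r, c = divmod(i, cols)
        PILImage.fromarray(to8(patches[i])).save(out / f"{slide_id}_patch_{i:04d}.png")
        lines.append(f"{slide_id},{i},{r},{c},{label}")
    (out / f"{slide_id}_manifest.csv").write_text("\n".join(lines) + "\n")
    (out / f"{slide_id}_ground_truth.json").write_text(
        json.dumps(
            {
                "slide_id": slide_id,
                "grid": list(image.grid),
                "patch_size": image.patch_size,
                "patch_labels": list(truth.patch_labels),
            },
            indent=2,
        )
    )
    return out
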