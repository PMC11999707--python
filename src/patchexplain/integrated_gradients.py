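"""Integrated Gradients with Riemann approximation and completeness checks.

The attribution of input component i is (x_i - x'_i) times the average of
df/dx_i along the straight-line path from a baseline x' (black image by
default) to the input x.  The path integral is approximated by an n-step
Riemann sum (midpoint rule by default, left rule available); pixel
attributions are aggregated to patch scores by signed sum over the
patch's pixels and channels.  For a differentiable model the patch
scores sum to f(x) - f(x') as n grows (the completeness axiom);
:func:`completeness_gap` measures the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, InputError
from .metrics import AttributionMap
from .models import ClassifierAdapter, PatchedImage

__all__ = ["IGConfig", "integrated_gradients", "completeness_gap"]


@dataclass(frozen=True)
class IGConfig:
    steps: int = 64
    baseline: np.ndarray | None = None  # None = black image
    rule: str = "midpoint"
    target: str = "logit"  # differentiate the class logit by default

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise InputError("steps must be >= 1")
        if self.rule not in ("left", "midpoint"):
            raise InputError(f"unknown Riemann rule {self.rule!r}")


def integrated_gradients(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    config: IGConfig | None = None,
) -> tuple[np.ndarray, AttributionMap]:
    """Pixel attribution map and its per-patch aggregation."""
    config = config or IGConfig()
    if "gradients" not in adapter.capabilities:
        raise CapabilityError("integrated gradients needs input gradients")
    x = image.pixels
    baseline = (
        np.zeros_like(x) if config.baseline is None else np.asarray(config.baseline, float)
    )
    if baseline.shape != x.shape:
        raise InputError("baseline shape must match the image")
    n = config.steps
    ts = (np.arange(n) + (0.5 if config.rule == "midpoint" else 0.0)) / n
    grad_sum = np.zeros_like(x)
    for t in ts:
        point = PatchedImage(baseline + t * (x - baseline), image.patch_size)
        grad_sum += adapter.gradient(point, class_index, target=config.target)
    pixel_map = (x - baseline) * grad_sum / n
    # pixel -> patch aggregation by signed sum over pixels and channels
    p = image.patch_size
    rows, cols = image.grid
    patch_scores = (
        pixel_map.reshape(rows, p, cols, p, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(image.d, -1)
        .sum(axis=1)
    )
    return pixel_map, AttributionMap(patch_scores, method="ig", class_index=class_index)


def completeness_gap(
    patch_scores: np.ndarray, f_x: float, f_baseline: float
) -> float:
    """|sum_i score_i - (f(x) - f(x'))| on the gradient-target scale."""
    return float(abs(np.asarray(patch_scores, float).sum() - (f_x - f_baseline)))
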