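"""RISE: randomized input sampling for explanation.

A patch is important when the model's class probability stays high in
expectation while other patches are randomly masked:

    score_i = E[ f_y(x . M) | M_i = 1 ]
            = E[ f_y(x . M) * M_i ] / E[M_i],

estimated by Monte-Carlo sampling of binary masks.  Two mask laws are
supported: independent Bernoulli(p) entries ("binomial" cardinalities)
and uniform cardinality (k uniform on {0..d}, then a uniform k-subset).
Masks act at patch/token resolution.  An exact 2^d enumeration oracle is
provided for small d.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import ConfigError, InputError, SizeError
from .metrics import AttributionMap
from .models import ClassifierAdapter, PatchedImage

__all__ = [
    "MaskBatch",
    "RiseConfig",
    "sample_masks",
    "rise_attribution",
    "exact_rise",
    "enumerate_masks",
]

BINOMIAL = "binomial"
UNIFORM_CARDINALITY = "uniform_cardinality"


@dataclass(frozen=True)
class MaskBatch:
    """Binary masks (n_masks x d) plus the sampling metadata that produced them."""

    masks: np.ndarray
    scheme: str
    seed: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 2 or m.size == 0:
            raise InputError("masks must be a non-empty n x d matrix")
        if not np.isin(m, (0, 1)).all():
            raise InputError("mask entries must be 0 or 1")
        object.__setattr__(self, "masks", m.astype(np.int8))

    @property
    def n_masks(self) -> int:
        return self.masks.shape[0]

    @property
    def d(self) -> int:
        return self.masks.shape[1]

    def cardinalities(self) -> np.ndarray:
        return self.masks.sum(axis=1)


@dataclass(frozen=True)
class RiseConfig:
    n_masks: int = 4000
    scheme: str = BINOMIAL
    p: float = 0.5
    masks_per_chunk: int = 512
    fill: float = 0.0
    zero_missing: bool = False  # score 0 (with warning) for never-included patches

    def __post_init__(self) -> None:
        if self.n_masks < 1 or self.masks_per_chunk < 1:
            raise ConfigError("n_masks and masks_per_chunk must be >= 1")
        if self.scheme == BINOMIAL and not 0.0 < self.p < 1.0:
            raise ConfigError("binomial p must lie in (0, 1)")
        if self.scheme not in (BINOMIAL, UNIFORM_CARDINALITY):
            raise ConfigError(f"unknown mask scheme {self.scheme!r}")


def sample_masks(
    n: int, d: int, scheme: str = BINOMIAL, seed: int = 0, p: float = 0.5
) -> MaskBatch:
    """Seed-reproducible mask sampling under either cardinality scheme."""
    if n < 1 or d < 1:
        raise InputError("n and d must be >= 1")
    rng = np.random.default_rng(seed)
    if scheme == BINOMIAL:
        if not 0.0 < p < 1.0:
            raise ConfigError("binomial p must lie in (0, 1)")
        masks = (rng.random((n, d)) < p).astype(np.int8)
    elif scheme == UNIFORM_CARDINALITY:
        k = rng.integers(0, d + 1, size=n)
        # rank of a uniform random key gives a uniform k-subset per row
        order = rng.random((n, d)).argsort(axis=1).argsort(axis=1)
        masks = (order < k[:, None]).astype(np.int8)
    else:
        raise ConfigError(f"unknown mask scheme {scheme!r}")
    return MaskBatch(masks, scheme, seed=seed, p=p if scheme == BINOMIAL else None)


def rise_attribution(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    config: RiseConfig | None = None,
    seed: int = 0,
    mask_batch: MaskBatch | None = None,
) -> AttributionMap:
    """Monte-Carlo RISE scores: empirical conditional mean of f_y given
    each patch being unmasked.

    Normalisation uses the empirical inclusion counts, so the estimator is
    the unbiased conditional mean even when counts fluctuate.  Evaluation
    is chunked by ``masks_per_chunk``; per-mask values are collected and
    reduced once, so the result is bitwise independent of the chunking.
    """
    config = config or RiseConfig()
    if mask_batch is None:
        mask_batch = sample_masks(
            config.n_masks, image.d, config.scheme, seed=seed, p=config.p
        )
    masks = mask_batch.masks
    if masks.shape[1] != image.d:
        raise InputError("mask width does not match the image grid")
    values = np.empty(masks.shape[0])
    for start in range(0, masks.shape[0], config.masks_per_chunk):
        chunk = masks[start : start + config.masks_per_chunk]
        values[start : start + chunk.shape[0]] = adapter.masked_predict_batch(
            image, chunk, config.fill
        )[:, class_index]
    counts = masks.sum(axis=0).astype(float)
    missing = counts == 0
    if missing.any() and not config.zero_missing:
        raise InputError(
            f"patches {np.flatnonzero(missing).tolist()} were never included; "
            "increase n_masks or enable zero_missing"
        )
    num = masks.T.astype(float) @ values
    scores = np.divide(num, counts, out=np.zeros_like(num), where=~missing)
    if missing.any():
        import warnings

        warnings.warn("never-included patches scored 0", stacklevel=2)
    method = f"rise-{'binomial' if mask_batch.scheme == BINOMIAL else 'uniform'}"
    return AttributionMap(
        scores,
        method=method,
        class_index=class_index,
        meta={"n_masks": int(masks.shape[0]), "scheme": mask_batch.scheme},
    )


def enumerate_masks(d: int) -> np.ndarray:
    """All 2^d binary masks as a (2^d, d) matrix; row index is the mask's
    little-endian integer encoding."""
    if d > 20:
        raise SizeError(f"refusing to enumerate 2^{d} masks")
    return ((np.arange(2**d)[:, None] >> np.arange(d)) & 1).astype(np.int8)


def mask_law(masks: np.ndarray, scheme: str, p: float = 0.5) -> np.ndarray:
    """P(M = m) for each mask row under the given scheme."""
    card = masks.sum(axis=1)
    d = masks.shape[1]
    if scheme == BINOMIAL:
        return p**card * (1.0 - p) ** (d - card)
    if scheme == UNIFORM_CARDINALITY:
        return np.array([1.0 / ((d + 1) * comb(d, int(k))) for k in card])
    raise ConfigError(f"unknown mask scheme {scheme!r}")


def exact_rise(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    scheme: str = BINOMIAL,
    p: float = 0.5,
    fill: float = 0.0,
    max_d: int = 14,
) -> AttributionMap:
    """Exact conditional expectation E[f_y(x . M) | M_i = 1] by full
    enumeration of the 2^d mask space (guarded to small d)."""
    d = image.d
    if d > max_d:
        raise SizeError(f"exact RISE enumeration guarded to d <= {max_d}, got {d}")
    masks = enumerate_masks(d)
    weights = mask_law(masks, scheme, p)
    values = adapter.masked_predict_batch(image, masks, fill)[:, class_index]
    num = masks.T.astype(float) @ (weights * values)
    den = masks.T.astype(float) @ weights
    return AttributionMap(
        num / den,
        method=f"rise-exact-{scheme}",
        class_index=class_index,
        meta={"scheme": scheme},
    )
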