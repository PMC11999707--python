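"""Classifier adapter contract and built-in reference models.

Every attribution method in this package talks to a classifier through
:class:`ClassifierAdapter`: class probabilities for (optionally masked)
inputs, per-layer attention matrices, and input gradients.  Two reference
models ship with the package so the whole suite runs without external
weights:

* :class:`LinearPatchScorer` — an analytic model whose score is a weighted
  sum of per-patch mean intensities.  Its induced cooperative game is
  additive, so exact Shapley values, integrated gradients and RISE scores
  all have closed forms; it is the oracle model for most tests.
* :class:`TinyViT` — a small randomly initialised vision transformer
  written in NumPy with hand-derived backpropagation, exposing
  probabilities, exact input gradients and head-averaged attention maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf, expit

from .errors import CapabilityError, InputError

__all__ = [
    "PatchedImage",
    "AttentionStack",
    "ClassifierAdapter",
    "LinearPatchScorer",
    "TinyViT",
    "MaskFunctionAdapter",
    "predict",
    "masked_predict",
    "attention_maps",
    "gradient",
    "ADAPTER_REGISTRY",
    "build_adapter",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchedImage:
    """An RGB image partitioned into a grid of square patches.

    The patch is the unit of masking and attribution: patch index ``i``
    maps row-major to grid cell ``(i // cols, i % cols)``.
    """

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    patch_size: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if self.patch_size < 1:
            raise InputError("patch_size must be positive")
        h, w, _ = px.shape
        if h % self.patch_size or w % self.patch_size:
            raise InputError(
                f"image {h}x{w} is not divisible into {self.patch_size}px patches"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def grid(self) -> tuple[int, int]:
        h, w, _ = self.pixels.shape
        return h // self.patch_size, w // self.patch_size

    @property
    def d(self) -> int:
        r, c = self.grid
        return r * c

    def patch_slices(self, i: int) -> tuple[slice, slice]:
        rows, cols = self.grid
        if not 0 <= i < rows * cols:
            raise InputError(f"patch index {i} out of range for d={rows * cols}")
        r, c = divmod(i, cols)
        p = self.patch_size
        return slice(r * p, (r + 1) * p), slice(c * p, (c + 1) * p)

    def patch_array(self) -> np.ndarray:
        """Patches as a (d, patch_size, patch_size, 3) array, row-major."""
        r, c = self.grid
        p = self.patch_size
        return (
            self.pixels.reshape(r, p, c, p, 3)
            .transpose(0, 2, 1, 3, 4)
            .reshape(r * c, p, p, 3)
        )

    def patch_mean_intensities(self) -> np.ndarray:
        """Mean over pixels and channels of each patch, length d."""
        return self.patch_array().mean(axis=(1, 2, 3))

    def apply_mask(self, mask: np.ndarray, fill: float = 0.0) -> "PatchedImage":
        """Replace every patch with ``mask[i] == 0`` by the fill value.

        An all-ones mask returns pixel data bit-identical to the input.
        """
        mask = _check_mask(mask, self.d)
        px = self.pixels.copy()
        for i in np.flatnonzero(mask == 0):
            rs, cs = self.patch_slices(int(i))
            px[rs, cs, :] = fill
        return PatchedImage(px, self.patch_size)


@dataclass(frozen=True)
class AttentionStack:
    """Head-averaged attention matrices, one (d+1)x(d+1) matrix per layer.

    Token 0 is the cls token by convention; rows are stochastic (each row
    says how much a token retrieves from every token of the layer below).
    """

    layers: np.ndarray  # (n_layers, d+1, d+1)
    cls_index: int = 0

    def __post_init__(self) -> None:
        mats = np.asarray(self.layers, dtype=float)
        if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
            raise InputError(f"expected (n, T, T) attention stack, got {mats.shape}")
        if np.any(mats < -1e-12):
            raise InputError("attention entries must be non-negative")
        rowsums = mats.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-5):
            raise InputError("attention rows must sum to 1 within 1e-5")
        object.__setattr__(self, "layers", mats)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_tokens(self) -> int:
        return self.layers.shape[1]

    @property
    def d(self) -> int:
        return self.n_tokens - 1


def _check_mask(mask: np.ndarray, d: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != (d,):
        raise InputError(f"mask length {mask.shape} does not match d={d}")
    if not np.isin(mask, (0, 1)).all():
        raise InputError("mask entries must be 0 or 1")
    return mask.astype(np.int8)


def _check_probs(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(axis=-1), 1.0, atol=atol).all():
        raise InputError("class probabilities must sum to 1")
    return p


# ---------------------------------------------------------------------------
# adapter contract
# ---------------------------------------------------------------------------


class ClassifierAdapter:
    """Contract every attribution method consumes.

    Subclasses set ``n_classes`` and ``capabilities`` (a frozenset drawn
    from {"probabilities", "gradients", "attentions"}) and implement
    :meth:`predict_proba`; the masked and batched entry points have
    generic implementations that mask pixels and re-predict.
    """

    n_classes: int = 2
    capabilities: frozenset[str] = frozenset({"probabilities"})

    # -- single image -------------------------------------------------
    def predict_proba(self, image: PatchedImage) -> np.ndarray:
        raise NotImplementedError

    def masked_predict(
        self, image: PatchedImage, mask: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        mask = _check_mask(mask, image.d)
        if mask.all():
            return self.predict_proba(image)
        return self.predict_proba(image.apply_mask(mask, fill))

    def masked_predict_batch(
        self, image: PatchedImage, masks: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks))
        return np.stack([self.masked_predict(image, m, fill) for m in masks])

    # -- optional capabilities ----------------------------------------
    def attention_maps(self, image: PatchedImage) -> AttentionStack:
        raise CapabilityError(f"{type(self).__name__} offers no attention maps")

    def gradient(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> np.ndarray:
        raise CapabilityError(f"{type(self).__name__} offers no gradients")

    def target_value(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> float:
        """The scalar the gradient differentiates (class logit or probability)."""
        raise CapabilityError(f"{type(self).__name__} offers no gradients")

    def _check_class(self, class_index: int) -> int:
        if not 0 <= class_index < self.n_classes:
            raise InputError(
                f"class index {class_index} out of range for {self.n_classes} classes"
            )
        return class_index


# ---------------------------------------------------------------------------
# free-function surface (validating wrappers)
# ---------------------------------------------------------------------------


def predict(
    adapter: ClassifierAdapter, images: Sequence[PatchedImage] | PatchedImage
) -> np.ndarray:
    """Class probabilities for a batch of same-shape images, rows sum to 1."""
    if "probabilities" not in adapter.capabilities:
        raise CapabilityError("adapter does not expose probabilities")
    if isinstance(images, PatchedImage):
        images = [images]
    shapes = {im.pixels.shape for im in images}
    if len(shapes) > 1:
        raise InputError(f"images in a batch must share a shape, got {shapes}")
    out = np.stack([adapter.predict_proba(im) for im in images])
    return _check_probs(out)


def masked_predict(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    mask: np.ndarray,
    fill: float = 0.0,
) -> np.ndarray:
    if "probabilities" not in adapter.capabilities:
        raise CapabilityError("adapter does not expose probabilities")
    return adapter.masked_predict(image, mask, fill)


def attention_maps(adapter: ClassifierAdapter, image: PatchedImage) -> AttentionStack:
    if "attentions" not in adapter.capabilities:
        raise CapabilityError("adapter does not expose attentions")
    return adapter.attention_maps(image)


def gradient(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    target: str = "logit",
) -> np.ndarray:
    if "gradients" not in adapter.capabilities:
        raise CapabilityError("adapter does not expose gradients")
    return adapter.gradient(image, class_index, target)


# ---------------------------------------------------------------------------
# linear patch scorer
# ---------------------------------------------------------------------------


class LinearPatchScorer(ClassifierAdapter):
    """Binary classifier scoring ``s = sum_i w_i * mean_intensity(patch i) + b``.

    Class-1 probability is ``s`` under the identity link (callers keep s in
    [0, 1] when probability semantics matter) or ``sigmoid(s)``.  The induced
    cooperative game is additive under the identity link, with exact Shapley
    value ``w_i * mean_intensity(patch i)`` per patch — the package's main
    analytic oracle.

    With ``attention_temperature`` set, the model also exposes a one-layer
    attention view in which the cls token attends to patches with weights
    ``softmax(contribution_i / temperature)`` — an attention-pooled reading
    of the same score, so attention-based attribution can run on it.
    """

    n_classes = 2

    def __init__(
        self,
        weights: np.ndarray,
        bias: float = 0.0,
        link: str = "identity",
        attention_temperature: float | None = None,
    ) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 1 or not np.isfinite(weights).all():
            raise InputError("weights must be a finite 1-d vector")
        if link not in ("identity", "sigmoid"):
            raise InputError(f"unknown link {link!r}")
        self.weights = weights
        self.bias = float(bias)
        self.link = link
        self.attention_temperature = attention_temperature
        caps = {"probabilities", "gradients"}
        if attention_temperature is not None:
            caps.add("attentions")
        self.capabilities = frozenset(caps)

    # -- internals -----------------------------------------------------
    def _contributions(self, image: PatchedImage) -> np.ndarray:
        if image.d != self.weights.size:
            raise InputError(
                f"image has d={image.d} patches, scorer expects {self.weights.size}"
            )
        return self.weights * image.patch_mean_intensities()

    def score(self, image: PatchedImage) -> float:
        return float(self._contributions(image).sum() + self.bias)

    def _link(self, s: np.ndarray | float) -> np.ndarray | float:
        return expit(s) if self.link == "sigmoid" else s

    # -- contract -------------------------------------------------------
    def predict_proba(self, image: PatchedImage) -> np.ndarray:
        p1 = self._link(self.score(image))
        return np.array([1.0 - p1, p1])

    def masked_predict_batch(
        self, image: PatchedImage, masks: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        """Vectorised masking: a masked patch's mean intensity is the fill."""
        masks = np.atleast_2d(np.asarray(masks)).astype(float)
        if masks.shape[1] != image.d:
            raise InputError(f"mask width {masks.shape[1]} != d={image.d}")
        contrib = self._contributions(image)
        s = masks @ contrib + (1.0 - masks) @ (self.weights * fill) + self.bias
        p1 = np.asarray(self._link(s), dtype=float)
        return np.stack([1.0 - p1, p1], axis=1)

    def gradient(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> np.ndarray:
        self._check_class(class_index)
        n_per_patch = image.patch_size**2 * 3  # mean over pixels and channels
        g = np.zeros_like(image.pixels)
        for i in range(image.d):
            rs, cs = image.patch_slices(i)
            g[rs, cs, :] = self.weights[i] / n_per_patch
        if target == "probability" and self.link == "sigmoid":
            p = expit(self.score(image))
            g = g * p * (1.0 - p)
        elif target not in ("logit", "probability"):
            raise InputError(f"unknown gradient target {target!r}")
        if class_index == 0:
            g = -g
        return g

    def target_value(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> float:
        self._check_class(class_index)
        s = self.score(image)
        if target == "probability":
            v = float(self._link(s)) if self.link == "sigmoid" else s
        else:
            v = s
        return v if class_index == 1 else -v

    def attention_maps(self, image: PatchedImage) -> AttentionStack:
        if self.attention_temperature is None:
            raise CapabilityError("scorer built without an attention view")
        contrib = self._contributions(image)
        z = contrib / self.attention_temperature
        z = z - z.max()
        a = np.exp(z)
        a /= a.sum()
        T = image.d + 1
        mat = np.eye(T)
        mat[0, 0] = 0.0
        mat[0, 1:] = a
        return AttentionStack(mat[None, :, :])


# ---------------------------------------------------------------------------
# mask-function adapter (toy games for metric tests)
# ---------------------------------------------------------------------------


class MaskFunctionAdapter(ClassifierAdapter):
    """Adapter whose class-1 output depends only on the binary patch mask.

    Wraps an arbitrary set function f: {0,1}^d -> R as a "classifier" so the
    metric and attribution code paths can be exercised on hand-computable
    games (class-0 output is 1 - f to keep the normalisation contract).
    """

    n_classes = 2
    capabilities = frozenset({"probabilities"})

    def __init__(self, fn, d: int) -> None:
        self.fn = fn
        self.d = d

    def predict_proba(self, image: PatchedImage) -> np.ndarray:
        return self.masked_predict(image, np.ones(self.d, dtype=np.int8))

    def masked_predict(
        self, image: PatchedImage, mask: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        mask = _check_mask(mask, self.d)
        v = float(self.fn(mask))
        return np.array([1.0 - v, v])

    def masked_predict_batch(
        self, image: PatchedImage, masks: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks))
        v = np.array([float(self.fn(m.astype(np.int8))) for m in masks])
        return np.stack([1.0 - v, v], axis=1)


# ---------------------------------------------------------------------------
# tiny NumPy vision transformer
# ---------------------------------------------------------------------------


def _layernorm_fwd(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy: np.ndarray, cache) -> np.ndarray:
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    return (dxhat - m1 - xhat * m2) * inv


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_bwd(a: np.ndarray, da: np.ndarray) -> np.ndarray:
    return a * (da - (da * a).sum(axis=-1, keepdims=True))


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return phi + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


class TinyViT(ClassifierAdapter):
    """Minimal pre-norm vision transformer in NumPy.

    Patch embedding + cls token + learned positions, ``depth`` blocks of
    multi-head self-attention and a GELU MLP (both pre-layernorm with
    residual connections), final layernorm and a linear head on the cls
    token.  Parameters are randomly initialised from ``seed``.  Forward
    passes cache activations so :meth:`gradient` can backpropagate exactly
    to the input pixels; attention maps are head-averaged post-softmax
    matrices, one per layer.
    """

    def __init__(
        self,
        image_size: tuple[int, int] | int,
        patch_size: int,
        depth: int = 2,
        heads: int = 2,
        embed_dim: int = 16,
        n_classes: int = 2,
        mlp_ratio: float = 2.0,
        seed: int = 0,
    ) -> None:
        if isinstance(image_size, int):
            image_size = (image_size, image_size)
        h, w = image_size
        if h % patch_size or w % patch_size:
            raise InputError("image size must be divisible by patch size")
        if embed_dim % heads:
            raise InputError("embed_dim must be divisible by heads")
        self.image_size = (h, w)
        self.patch_size = patch_size
        self.grid = (h // patch_size, w // patch_size)
        self.d = self.grid[0] * self.grid[1]
        self.depth = depth
        self.heads = heads
        self.embed_dim = embed_dim
        self.n_classes = n_classes
        self.seed = seed
        self.capabilities = frozenset({"probabilities", "gradients", "attentions"})

        rng = np.random.default_rng(seed)
        D = embed_dim
        F = patch_size * patch_size * 3
        M = int(round(mlp_ratio * D))
        s = 1.0 / np.sqrt(D)

        def mat(*shape, scale=s):
            return rng.normal(0.0, scale, size=shape)

        self.we = mat(F, D, scale=1.0 / np.sqrt(F))
        self.be = np.zeros(D)
        self.cls = mat(D)
        self.pos = mat(self.d + 1, D, scale=0.02)
        self.blocks = []
        for _ in range(depth):
            self.blocks.append(
                {
                    "ln1_g": np.ones(D),
                    "ln1_b": np.zeros(D),
                    "wq": mat(D, D),
                    "bq": np.zeros(D),
                    "wk": mat(D, D),
                    "bk": np.zeros(D),
                    "wv": mat(D, D),
                    "bv": np.zeros(D),
                    "wo": mat(D, D),
                    "bo": np.zeros(D),
                    "ln2_g": np.ones(D),
                    "ln2_b": np.zeros(D),
                    "w1": mat(D, M, scale=1.0 / np.sqrt(D)),
                    "b1": np.zeros(M),
                    "w2": mat(M, D, scale=1.0 / np.sqrt(M)),
                    "b2": np.zeros(D),
                }
            )
        self.lnf_g = np.ones(D)
        self.lnf_b = np.zeros(D)
        self.wh = mat(D, n_classes)
        self.bh = np.zeros(n_classes)

    # -- forward --------------------------------------------------------
    def _check_image(self, image: PatchedImage) -> None:
        if image.pixels.shape[:2] != self.image_size:
            raise InputError(
                f"image shape {image.pixels.shape[:2]} != model {self.image_size}"
            )
        if image.patch_size != self.patch_size:
            raise InputError("image patch size does not match the model")

    def _forward(self, pixels: np.ndarray) -> dict:
        p = self.patch_size
        gr, gc = self.grid
        patches = (
            pixels.reshape(gr, p, gc, p, 3).transpose(0, 2, 1, 3, 4).reshape(self.d, -1)
        )
        X = np.vstack([self.cls, patches @ self.we + self.be]) + self.pos
        cache: dict = {"patches": patches, "layers": [], "attn": []}
        h, dh = self.heads, self.embed_dim // self.heads
        T = self.d + 1
        for blk in self.blocks:
            lc: dict = {"X_in": X}
            Y, lnc1 = _layernorm_fwd(X, blk["ln1_g"], blk["ln1_b"])
            Q = (Y @ blk["wq"] + blk["bq"]).reshape(T, h, dh).transpose(1, 0, 2)
            K = (Y @ blk["wk"] + blk["bk"]).reshape(T, h, dh).transpose(1, 0, 2)
            V = (Y @ blk["wv"] + blk["bv"]).reshape(T, h, dh).transpose(1, 0, 2)
            S = Q @ K.transpose(0, 2, 1) / np.sqrt(dh)
            A = _softmax(S)
            O = (A @ V).transpose(1, 0, 2).reshape(T, self.embed_dim)
            attn_out = O @ blk["wo"] + blk["bo"]
            X2 = X + attn_out
            Z, lnc2 = _layernorm_fwd(X2, blk["ln2_g"], blk["ln2_b"])
            H1 = Z @ blk["w1"] + blk["b1"]
            G = _gelu(H1)
            X = X2 + G @ blk["w2"] + blk["b2"]
            lc.update(lnc1=lnc1, Q=Q, K=K, V=V, A=A, X2=X2, lnc2=lnc2, H1=H1, G=G)
            cache["layers"].append(lc)
            cache["attn"].append(A.mean(axis=0))
        Xf, lncf = _layernorm_fwd(X, self.lnf_g, self.lnf_b)
        logits = Xf[0] @ self.wh + self.bh
        cache.update(lncf=lncf, logits=logits, probs=_softmax(logits))
        return cache

    def predict_proba(self, image: PatchedImage) -> np.ndarray:
        self._check_image(image)
        return self._forward(image.pixels)["probs"]

    def attention_maps(self, image: PatchedImage) -> AttentionStack:
        self._check_image(image)
        return AttentionStack(np.stack(self._forward(image.pixels)["attn"]))

    def logits(self, image: PatchedImage) -> np.ndarray:
        self._check_image(image)
        return self._forward(image.pixels)["logits"]

    def target_value(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> float:
        self._check_class(class_index)
        c = self._forward(image.pixels)
        key = "probs" if target == "probability" else "logits"
        return float(c[key][class_index])

    # -- backward -------------------------------------------------------
    def gradient(
        self, image: PatchedImage, class_index: int, target: str = "logit"
    ) -> np.ndarray:
        self._check_class(class_index)
        self._check_image(image)
        if target not in ("logit", "probability"):
            raise InputError(f"unknown gradient target {target!r}")
        c = self._forward(image.pixels)
        if target == "logit":
            dlogits = np.zeros(self.n_classes)
            dlogits[class_index] = 1.0
        else:
            p = c["probs"]
            dlogits = -p[class_index] * p
            dlogits[class_index] += p[class_index]
        h, dh = self.heads, self.embed_dim // self.heads
        T = self.d + 1
        dXf = np.zeros((T, self.embed_dim))
        dXf[0] = self.wh @ dlogits
        dX = _layernorm_bwd(dXf, c["lncf"])
        for blk, lc in zip(reversed(self.blocks), reversed(c["layers"])):
            dG = dX @ blk["w2"].T
            dH1 = dG * _gelu_grad(lc["H1"])
            dZ = dH1 @ blk["w1"].T
            dX2 = dX + _layernorm_bwd(dZ, lc["lnc2"])
            dO = (dX2 @ blk["wo"].T).reshape(T, h, dh).transpose(1, 0, 2)
            dA = dO @ lc["V"].transpose(0, 2, 1)
            dV = lc["A"].transpose(0, 2, 1) @ dO
            dS = _softmax_bwd(lc["A"], dA) / np.sqrt(dh)
            dQ = dS @ lc["K"]
            dK = dS.transpose(0, 2, 1) @ lc["Q"]
            dY = (
                dQ.transpose(1, 0, 2).reshape(T, -1) @ blk["wq"].T
                + dK.transpose(1, 0, 2).reshape(T, -1) @ blk["wk"].T
                + dV.transpose(1, 0, 2).reshape(T, -1) @ blk["wv"].T
            )
            dX = dX2 + _layernorm_bwd(dY, lc["lnc1"])
        dpatches = dX[1:] @ self.we.T  # (d, p*p*3)
        p = self.patch_size
        gr, gc = self.grid
        return (
            dpatches.reshape(gr, gc, p, p, 3)
            .transpose(0, 2, 1, 3, 4)
            .reshape(self.image_size[0], self.image_size[1], 3)
        )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def _build_linear(spec: dict) -> ClassifierAdapter:
    return LinearPatchScorer(
        weights=np.asarray(spec["weights"], dtype=float),
        bias=spec.get("bias", 0.0),
        link=spec.get("link", "identity"),
        attention_temperature=spec.get("attention_temperature"),
    )


def _build_tiny_vit(spec: dict) -> ClassifierAdapter:
    return TinyViT(
        image_size=tuple(np.atleast_1d(spec["image_size"]).tolist() * 2)[:2]
        if np.isscalar(spec["image_size"])
        else tuple(spec["image_size"]),
        patch_size=spec["patch_size"],
        depth=spec.get("depth", 2),
        heads=spec.get("heads", 2),
        embed_dim=spec.get("embed_dim", 16),
        n_classes=spec.get("n_classes", 2),
        seed=spec.get("seed", 0),
    )


ADAPTER_REGISTRY = {"linear": _build_linear, "tiny-vit": _build_tiny_vit}


def build_adapter(spec: dict) -> ClassifierAdapter:
    """Construct an adapter from a configuration mapping with a ``kind`` key."""
    kind = spec.get("kind")
    if kind not in ADAPTER_REGISTRY:
        raise InputError(f"unknown adapter kind {kind!r}; have {sorted(ADAPTER_REGISTRY)}")
    return ADAPTER_REGISTRY[kind]({k: v for k, v in spec.items() if k != "kind"})
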