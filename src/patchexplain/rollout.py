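"""Attention Rollout attribution, with and without residual correction.

Rollout treats the per-layer attention matrices as a layered flow graph:
the importance of patch token i is the total weight of all paths from i
to the cls token, which collapses to the cls row of the layer-wise matrix
product A_n @ ... @ A_1.  The residual variant first replaces each A_l by
the row-renormalised A_l + I, modelling the skip connection around the
attention block.  A brute-force path enumeration oracle is provided for
small stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np

from .errors import InputError, SizeError
from .metrics import AttributionMap
from .models import AttentionStack

__all__ = ["RolloutConfig", "rollout_attribution", "rollout_matrix", "path_flow_oracle"]


@dataclass(frozen=True)
class RolloutConfig:
    residual: bool = False
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.renormalize and not self.residual:
            # renormalisation only has meaning after adding the identity
            object.__setattr__(self, "renormalize", False)


def _prepared_layers(stack: AttentionStack, config: RolloutConfig) -> np.ndarray:
    mats = stack.layers
    if config.residual:
        mats = mats + np.eye(stack.n_tokens)
        if config.renormalize:
            mats = mats / mats.sum(axis=2, keepdims=True)
    return mats


def rollout_matrix(stack: AttentionStack, config: RolloutConfig | None = None) -> np.ndarray:
    """The full (d+1)x(d+1) product A_n @ ... @ A_1 (layers applied in order)."""
    config = config or RolloutConfig()
    if stack.n_layers == 0:
        raise InputError("attention stack is empty")
    out = np.eye(stack.n_tokens)
    for mat in _prepared_layers(stack, config):
        out = mat @ out
    return out


def rollout_attribution(
    stack: AttentionStack, config: RolloutConfig | None = None
) -> AttributionMap:
    """Per-patch rollout scores: the cls row of the product, cls column dropped.

    Without the residual the full (d+1)-token score vector sums to 1,
    since a product of row-stochastic matrices is row-stochastic.
    """
    config = config or RolloutConfig()
    full = rollout_matrix(stack, config)[stack.cls_index]
    scores = np.delete(full, stack.cls_index)
    method = "rollout-res" if config.residual else "rollout"
    return AttributionMap(scores, method=method)


def path_flow_oracle(
    stack: AttentionStack,
    config: RolloutConfig | None = None,
    max_paths: int = 500_000,
) -> np.ndarray:
    """Sum of path-weight products from every source token to cls, by
    explicit enumeration of all layered paths.

    The flow of a path (i_0, ..., i_n) ending at cls is the product of the
    traversed edge weights A_l[i_l, i_{l-1}]; the per-source totals equal
    the cls row of the matrix-product rollout exactly.  Guarded to small
    stacks (the path count grows as (d+1)^(n-1) per source).
    """
    config = config or RolloutConfig()
    mats = _prepared_layers(stack, config)
    n, T = stack.n_layers, stack.n_tokens
    if T ** max(n - 1, 0) * T > max_paths:
        raise SizeError(
            f"path enumeration over {T} tokens x {n} layers exceeds the guard"
        )
    flows = np.zeros(T)
    cls = stack.cls_index
    for source in range(T):
        total = 0.0
        for inner in iter_product(range(T), repeat=n - 1):
            nodes = (source, *inner, cls)
            w = 1.0
            for l in range(n):
                w *= mats[l][nodes[l + 1], nodes[l]]
            total += w
        flows[source] = total
    return flows
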