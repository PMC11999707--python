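"""Shapley-value attribution for patch games.

The image game is v(m) = f_y(x . m) - f_y(0): a coalition of patches is
kept, everything else masked, and the payoff is the shift of the class-y
probability away from the fully masked baseline.  Player i's Shapley
value averages its marginal contribution v(m + e_i) - v(m) over coalition
sizes, weighting every size equally:

    phi_i = (1/d) * sum_{m : m_i = 0} C(d-1, |m|)^-1 (v(m + e_i) - v(m)).

Three estimators are provided:

* :func:`exact_shapley` — full 2^d enumeration (guarded to small d);
* :func:`regression_shapley` — the weighted-least-squares
  characterisation: phi minimises E_psh[(v(m) - m' phi)^2] subject to
  1' phi = v(1), with the Shapley kernel
  psh(m) proportional to (|m| - 1)! (d - |m| - 1)! on 0 < |m| < d;
* a toy amortised explainer trained on the same objective, whose forward
  pass always ends with additive efficient normalisation so efficiency
  holds by construction.

The surrogate-training ingredients (the uniform-cardinality mask law
p(m) = 1 / (C(d, |m|) (d + 1)) and the KL matching objective) are also
implemented and tested at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, factorial

import numpy as np

from .errors import ConfigError, InputError, SizeError, SolverError, TrainingError
from .metrics import AttributionMap
from .models import ClassifierAdapter, PatchedImage
from .rise import MaskBatch, enumerate_masks

__all__ = [
    "CooperativeGame",
    "ShapleyResult",
    "KernelWeights",
    "exact_shapley",
    "shapley_kernel",
    "regression_shapley",
    "additive_efficient_normalization",
    "make_image_game",
    "surrogate_mask_law",
    "sample_surrogate_masks",
    "surrogate_objective",
    "ExplainerModel",
    "ExplainerTrainConfig",
    "train_explainer",
    "singleton_features",
    "random_additive_games",
]

ENUMERATION_GUARD = 14


# ---------------------------------------------------------------------------
# games
# ---------------------------------------------------------------------------


class CooperativeGame:
    """A set function v over coalitions of d players with v(0) = 0."""

    def __init__(self, d: int, evaluate_batch_fn, name: str = "") -> None:
        if d < 1:
            raise InputError("a game needs at least one player")
        self.d = d
        self._evaluate_batch = evaluate_batch_fn
        self.name = name

    def evaluate(self, mask: np.ndarray) -> float:
        return float(self.evaluate_batch(np.atleast_2d(mask))[0])

    def evaluate_batch(self, masks: np.ndarray) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks))
        if masks.shape[1] != self.d:
            raise InputError(f"mask width {masks.shape[1]} != d={self.d}")
        return np.asarray(self._evaluate_batch(masks), dtype=float)

    def grand_value(self) -> float:
        return self.evaluate(np.ones(self.d, dtype=np.int8))

    def check_baseline(self, atol: float = 1e-9) -> None:
        v0 = self.evaluate(np.zeros(self.d, dtype=np.int8))
        if abs(v0) > atol:
            raise InputError(f"game violates v(0)=0: v(0)={v0!r}")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_function(cls, fn, d: int, name: str = "") -> "CooperativeGame":
        def batch(masks):
            return np.array([float(fn(m.astype(np.int8))) for m in masks])

        return cls(d, batch, name)

    @classmethod
    def additive(cls, contributions: np.ndarray, name: str = "additive") -> "CooperativeGame":
        c = np.asarray(contributions, dtype=float)
        game = cls(c.size, lambda masks: np.asarray(masks, float) @ c, name)
        game.contributions = c
        return game


def make_image_game(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    fill: float = 0.0,
) -> CooperativeGame:
    """v(m) = f_y(x . m) - f_y(0); subtracting the fully masked baseline
    prediction enforces v(0) = 0."""
    if "probabilities" not in adapter.capabilities:
        raise InputError("image games need an adapter with probabilities")
    if not 0 <= class_index < adapter.n_classes:
        raise InputError(f"invalid class index {class_index}")
    d = image.d
    f0 = float(
        adapter.masked_predict(image, np.zeros(d, dtype=np.int8), fill)[class_index]
    )

    def batch(masks):
        return adapter.masked_predict_batch(image, masks, fill)[:, class_index] - f0

    game = CooperativeGame(d, batch, name=f"image-game-y{class_index}")
    game.baseline_prediction = f0
    return game


# ---------------------------------------------------------------------------
# results and normalisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapleyResult:
    phi: np.ndarray
    grand_value: float
    normalized: bool = True
    method: str = "shapley"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))

    @property
    def d(self) -> int:
        return self.phi.size

    def efficiency_gap(self) -> float:
        return float(abs(self.phi.sum() - self.grand_value))

    def as_map(self, **kwargs) -> AttributionMap:
        return AttributionMap(self.phi, method=self.method, **kwargs)


def additive_efficient_normalization(phi: np.ndarray, grand_value: float) -> np.ndarray:
    """Shift every coordinate by (v(1) - sum(phi)) / d so the result sums
    to the grand value exactly; idempotent."""
    phi = np.asarray(phi, dtype=float)
    return phi + (grand_value - phi.sum()) / phi.size


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------


def exact_shapley(game: CooperativeGame, max_d: int = ENUMERATION_GUARD) -> ShapleyResult:
    """Shapley values by full 2^d enumeration of marginal contributions."""
    d = game.d
    if d > max_d:
        raise SizeError(f"exact Shapley guarded to d <= {max_d}, got {d}")
    game.check_baseline()
    masks = enumerate_masks(d)
    v = game.evaluate_batch(masks)
    card = masks.sum(axis=1)
    phi = np.empty(d)
    for i in range(d):
        absent = np.flatnonzero(masks[:, i] == 0)
        partner = absent + (1 << i)  # same coalition with player i added
        w = 1.0 / np.array([comb(d - 1, int(k)) for k in card[absent]])
        phi[i] = float(w @ (v[partner] - v[absent])) / d
    return ShapleyResult(
        phi, grand_value=float(v[-1]), normalized=True, method="shapley-exact"
    )


# ---------------------------------------------------------------------------
# kernels and mask laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelWeights:
    """A mask law given by one weight per mask of each cardinality.

    ``per_mask[k]`` is the probability (or normalised kernel weight) of any
    single mask with |m| = k, so the cardinality pmf is
    ``per_mask[k] * C(d, k)`` and the law sums to 1 over all 2^d masks.
    """

    d: int
    per_mask: np.ndarray  # length d + 1
    kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_mask", np.asarray(self.per_mask, dtype=float))

    def cardinality_pmf(self) -> np.ndarray:
        return self.per_mask * np.array([comb(self.d, k) for k in range(self.d + 1)])

    def mask_probability(self, masks: np.ndarray) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks))
        return self.per_mask[masks.sum(axis=1)]

    def total_mass(self) -> float:
        """Sum over all 2^d masks (exact by cardinality counting)."""
        return float(self.cardinality_pmf().sum())

    def sample(self, n: int, seed: int = 0) -> MaskBatch:
        """Draw a cardinality from the pmf, then a uniform subset of that size."""
        rng = np.random.default_rng(seed)
        pmf = self.cardinality_pmf()
        k = rng.choice(self.d + 1, size=n, p=pmf / pmf.sum())
        order = rng.random((n, self.d)).argsort(axis=1).argsort(axis=1)
        masks = (order < k[:, None]).astype(np.int8)
        return MaskBatch(masks, scheme=self.kind, seed=seed)


def shapley_kernel(d: int) -> KernelWeights:
    """The Shapley kernel psh(m) proportional to (|m|-1)! (d-|m|-1)! on
    0 < |m| < d, zero on the empty and full masks, normalised over 2^d
    masks with exact rational arithmetic."""
    if d < 2:
        raise InputError("the Shapley kernel needs d >= 2")
    raw = [Fraction(0)] * (d + 1)
    for k in range(1, d):
        raw[k] = Fraction(factorial(k - 1) * factorial(d - k - 1))
    total = sum(comb(d, k) * raw[k] for k in range(d + 1))
    return KernelWeights(d, np.array([float(w / total) for w in raw]), kind="psh")


def surrogate_mask_law(d: int) -> KernelWeights:
    """The surrogate-training mask law p(m) = 1 / (C(d,|m|) (d+1)):
    a uniform cardinality followed by a uniform subset of that size."""
    if d < 1:
        raise InputError("d must be >= 1")
    per = np.array([1.0 / (comb(d, k) * (d + 1)) for k in range(d + 1)])
    return KernelWeights(d, per, kind="surrogate")


def sample_surrogate_masks(n: int, d: int, seed: int = 0) -> MaskBatch:
    return surrogate_mask_law(d).sample(n, seed)


def surrogate_objective(teacher_probs: np.ndarray, student_probs: np.ndarray) -> float:
    """KL divergence D(teacher || student) between class distributions;
    the per-example surrogate matching loss."""
    t = np.asarray(teacher_probs, dtype=float)
    s = np.asarray(student_probs, dtype=float)
    for name, p in (("teacher", t), ("student", s)):
        if p.ndim != 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise InputError(f"{name} probabilities are not a normalised distribution")
    mask = t > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(t[mask] * (np.log(t[mask]) - np.log(s[mask]))))


# ---------------------------------------------------------------------------
# regression estimator
# ---------------------------------------------------------------------------


def regression_shapley(
    game: CooperativeGame,
    masks: np.ndarray | MaskBatch | None = None,
    weights: np.ndarray | None = None,
    n_masks: int = 2048,
    seed: int = 0,
    exhaustive: bool = False,
) -> ShapleyResult:
    """Constrained weighted least squares on coalition values.

    With ``exhaustive=True`` the design is every admissible mask
    (0 < |m| < d) weighted by the exact Shapley kernel, which reproduces
    the enumeration definition exactly; otherwise masks are drawn from the
    kernel (or supplied) and weighted uniformly.  The efficiency
    constraint 1' phi = v(1) is eliminated through the KKT system, so it
    holds on return up to the final additive renormalisation.
    """
    d = game.d
    game.check_baseline()
    if exhaustive:
        if d > ENUMERATION_GUARD:
            raise SizeError(f"exhaustive design guarded to d <= {ENUMERATION_GUARD}")
        all_masks = enumerate_masks(d)
        card = all_masks.sum(axis=1)
        keep = (card > 0) & (card < d)
        design = all_masks[keep]
        weights = shapley_kernel(d).mask_probability(design)
    else:
        if masks is None:
            design = shapley_kernel(d).sample(n_masks, seed).masks
        else:
            design = masks.masks if isinstance(masks, MaskBatch) else np.asarray(masks)
        card = design.sum(axis=1)
        admissible = (card > 0) & (card < d)
        design = design[admissible]
        if weights is None:
            weights = np.ones(design.shape[0])
        else:
            weights = np.asarray(weights, dtype=float)[admissible]
    if design.shape[0] < d + 1:
        raise SolverError(
            f"{design.shape[0]} admissible masks is too few for d={d} (need >= d+1)"
        )
    v = game.evaluate_batch(design)
    v1 = game.grand_value()
    M = design.astype(float)
    W = weights / weights.sum()
    A = M.T @ (M * W[:, None])
    b = M.T @ (W * v)
    ones = np.ones(d)
    kkt = np.zeros((d + 1, d + 1))
    kkt[:d, :d] = 2.0 * A
    kkt[:d, d] = ones
    kkt[d, :d] = ones
    rhs = np.concatenate([2.0 * b, [v1]])
    if np.linalg.matrix_rank(kkt) < d + 1:
        raise SolverError(
            "rank-deficient constrained least-squares system; "
            f"design has {design.shape[0]} masks over d={d} players"
        )
    phi = np.linalg.solve(kkt, rhs)[:d]
    phi = additive_efficient_normalization(phi, v1)
    return ShapleyResult(
        phi,
        grand_value=v1,
        normalized=True,
        method="shapley-regression",
        meta={"n_masks": int(design.shape[0]), "exhaustive": exhaustive},
    )


# ---------------------------------------------------------------------------
# toy amortised explainer
# ---------------------------------------------------------------------------


class ExplainerModel:
    """Per-patch affine explainer phi_i = a_i * c_i + b_i over game
    features c, always followed by additive efficient normalisation, so
    every forward output satisfies 1' phi = v(1) by construction."""

    def __init__(self, d: int, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.d = d
        self.scale = 0.5 + 0.1 * rng.standard_normal(d)
        self.bias = 0.01 * rng.standard_normal(d)

    def forward(self, features: np.ndarray, grand_value: float) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        raw = self.scale * features + self.bias
        return additive_efficient_normalization(raw, grand_value)

    def parameters(self) -> dict[str, np.ndarray]:
        return {"scale": self.scale, "bias": self.bias}


@dataclass(frozen=True)
class ExplainerTrainConfig:
    epochs: int = 60
    masks_per_step: int = 32
    lr: float = 0.05
    seed: int = 0


def singleton_features(game: CooperativeGame) -> np.ndarray:
    """Per-patch singleton coalition values v(e_i), the explainer's input
    summary of a game."""
    return game.evaluate_batch(np.eye(game.d, dtype=np.int8))


def random_additive_games(
    n: int, d: int, seed: int = 0, scale: float = 1.0
) -> list[CooperativeGame]:
    rng = np.random.default_rng(seed)
    return [
        CooperativeGame.additive(rng.uniform(-scale, scale, size=d), name=f"additive-{i}")
        for i in range(n)
    ]


def train_explainer(
    games: list[CooperativeGame],
    explainer: ExplainerModel,
    kernel: KernelWeights | None = None,
    config: ExplainerTrainConfig | None = None,
    features: list[np.ndarray] | None = None,
) -> tuple[ExplainerModel, list[float]]:
    """Fit the explainer on E_psh[(v(m) - m' phi_hat)^2] with Adam.

    Masks are redrawn from the Shapley kernel every step; the efficiency
    side constraint is handled by the normalisation inside the forward
    pass (its Jacobian, I - 11'/d, is part of the gradient).  Returns the
    model and the per-epoch mean loss trace.
    """
    if not games:
        raise InputError("no games to train on")
    d = explainer.d
    kernel = kernel or shapley_kernel(d)
    config = config or ExplainerTrainConfig()
    if features is None:
        features = [singleton_features(g) for g in games]
    grand = [g.grand_value() for g in games]
    rng = np.random.default_rng(config.seed)
    # Adam state
    m = {k: np.zeros(d) for k in ("scale", "bias")}
    s = {k: np.zeros(d) for k in ("scale", "bias")}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []
    for _ in range(config.epochs):
        losses = []
        for gi in rng.permutation(len(games)):
            g, c, v1 = games[gi], features[gi], grand[gi]
            batch = kernel.sample(config.masks_per_step, seed=int(rng.integers(2**31)))
            M = batch.masks.astype(float)
            v = g.evaluate_batch(batch.masks)
            phi = explainer.forward(c, v1)
            r = v - M @ phi
            loss = float(np.mean(r**2))
            if not np.isfinite(loss):
                raise TrainingError("explainer training diverged (non-finite loss)")
            losses.append(loss)
            dphi = -2.0 * (M.T @ r) / M.shape[0]
            draw = dphi - dphi.mean()  # Jacobian of the normalisation
            grads = {"scale": draw * c, "bias": draw}
            step += 1
            for k in ("scale", "bias"):
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                s[k] = beta2 * s[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                shat = s[k] / (1 - beta2**step)
                getattr(explainer, k)[:] -= config.lr * mhat / (np.sqrt(shat) + eps)
        trace.append(float(np.mean(losses)))
    return explainer, trace
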