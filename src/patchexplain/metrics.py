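"""Insertion/Deletion faithfulness metrics and statistical comparison.

An attribution map is argsorted into a patch ranking.  Insertion starts
from a fully masked image and reveals patches from most to least
important, recording the model's class probability after each step;
Deletion starts from the full image and masks patches in the same order.
Both curves are summarised by the trapezoidal area under the curve over
the revealed/removed patch fraction: higher Insertion AUC and lower
Deletion AUC mean a more faithful ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .models import ClassifierAdapter, PatchedImage

__all__ = [
    "AttributionMap",
    "Curve",
    "rank_patches",
    "insertion_curve",
    "deletion_curve",
    "random_baseline",
    "aggregate",
    "welch_t_matrix",
    "top_k_precision",
]


@dataclass(frozen=True)
class AttributionMap:
    """One real importance score per patch, with method provenance."""

    scores: np.ndarray
    method: str = ""
    image_id: str = ""
    slide_id: str = ""
    class_index: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise InputError("attribution scores must be a 1-d vector")
        object.__setattr__(self, "scores", s)

    @property
    def d(self) -> int:
        return self.scores.size

    def ranking(self) -> np.ndarray:
        return rank_patches(self)


@dataclass(frozen=True)
class Curve:
    """(#patches, class probability) points for #p = 0..d plus their AUC."""

    points: np.ndarray  # (d+1, 2): column 0 = #patches, column 1 = probability
    auc: float

    @property
    def values(self) -> np.ndarray:
        return self.points[:, 1]


def rank_patches(map_or_scores: AttributionMap | np.ndarray) -> np.ndarray:
    """Patch indices in descending score order; ties broken by ascending
    patch index (stable argsort of the negated scores)."""
    scores = (
        map_or_scores.scores
        if isinstance(map_or_scores, AttributionMap)
        else np.asarray(map_or_scores, dtype=float)
    )
    if np.isnan(scores).any():
        raise InputError("attribution scores contain NaN")
    return np.argsort(-scores, kind="stable")


def _check_ranking(ranking: np.ndarray, d: int) -> np.ndarray:
    ranking = np.asarray(ranking, dtype=int)
    if sorted(ranking.tolist()) != list(range(d)):
        raise InputError(f"ranking is not a permutation of 0..{d - 1}")
    return ranking


def _step_masks(ranking: np.ndarray, d: int, insertion: bool) -> np.ndarray:
    """Mask for each step #p = 0..d; insertion keeps the top-#p patches,
    deletion removes them."""
    masks = np.zeros((d + 1, d), dtype=np.int8) if insertion else np.ones(
        (d + 1, d), dtype=np.int8
    )
    for p in range(1, d + 1):
        masks[p] = masks[p - 1]
        masks[p, ranking[p - 1]] = 1 if insertion else 0
    return masks


def _curve(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    ranking: np.ndarray,
    fill: float,
    insertion: bool,
) -> Curve:
    d = image.d
    ranking = _check_ranking(ranking, d)
    masks = _step_masks(ranking, d, insertion)
    values = adapter.masked_predict_batch(image, masks, fill)[:, class_index]
    x = np.arange(d + 1) / d
    auc = float(np.trapezoid(values, x))
    return Curve(np.column_stack([np.arange(d + 1), values]), auc)


def insertion_curve(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    ranking: np.ndarray,
    fill: float = 0.0,
) -> Curve:
    """Reveal patches most-important-first from a fully masked image."""
    return _curve(adapter, image, class_index, ranking, fill, insertion=True)


def deletion_curve(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    ranking: np.ndarray,
    fill: float = 0.0,
) -> Curve:
    """Mask patches most-important-first starting from the full image."""
    return _curve(adapter, image, class_index, ranking, fill, insertion=False)


def random_baseline(
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int,
    n_repeats: int = 20,
    seed: int = 0,
    fill: float = 0.0,
) -> tuple[float, float]:
    """Mean insertion and deletion AUC over uniformly random rankings."""
    if n_repeats < 1:
        raise InputError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    ins, dele = [], []
    for _ in range(n_repeats):
        ranking = rng.permutation(image.d)
        ins.append(insertion_curve(adapter, image, class_index, ranking, fill).auc)
        dele.append(deletion_curve(adapter, image, class_index, ranking, fill).auc)
    return float(np.mean(ins)), float(np.mean(dele))


def aggregate(per_patch: list[tuple[str, float]], mode: str = "per_patch") -> float:
    """Summarise (slide_id, auc) pairs.

    ``per_patch`` is the grand mean of all AUCs; ``per_slide`` first
    averages within each slide, then across slides, weighting slides
    equally regardless of how many patches they contributed.
    """
    if not per_patch:
        raise InputError("nothing to aggregate")
    df = pd.DataFrame(per_patch, columns=["slide_id", "auc"])
    if mode == "per_patch":
        return float(df["auc"].mean())
    if mode == "per_slide":
        return float(df.groupby("slide_id")["auc"].mean().mean())
    raise InputError(f"unknown aggregation mode {mode!r}")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        # degenerate: no variance on either side
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical samples trip scipy's moment precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def welch_t_matrix(populations: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Welch (unequal variance) t-test p-values.

    No multiplicity correction is applied; the diagonal is NaN.
    """
    for name, pop in populations.items():
        if np.asarray(pop).size < 2:
            raise InputError(f"population {name!r} needs at least 2 samples")
    names = list(populations)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in combinations(names, 2):
        p = _welch_p(np.asarray(populations[a], float), np.asarray(populations[b], float))
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def top_k_precision(scores: np.ndarray, positive_indices: np.ndarray, k: int | None = None) -> float:
    """Fraction of the k top-ranked patches that are planted positives."""
    positive = set(int(i) for i in np.asarray(positive_indices).ravel())
    if k is None:
        k = len(positive)
    if k == 0:
        raise InputError("no positive patches to score against")
    top = rank_patches(np.asarray(scores, dtype=float))[:k]
    return float(sum(1 for i in top if int(i) in positive) / k)
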