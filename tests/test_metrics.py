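"""Insertion/deletion curves, aggregation and Welch comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import stdtr

from patchexplain import PatchedImage
from patchexplain.errors import InputError
from patchexplain.metrics import (
    AttributionMap,
    aggregate,
    deletion_curve,
    insertion_curve,
    random_baseline,
    rank_patches,
    top_k_precision,
    welch_t_matrix,
)
from patchexplain.models import MaskFunctionAdapter
from patchexplain.synthetic import make_linear_patch_scorer


def toy_image(d):
    return PatchedImage(np.full((1, d, 3), 0.5), 1)


# -- ranking ------------------------------------------------------------


def test_rank_descending():
    assert rank_patches(np.array([0.1, 0.9, 0.5])).tolist() == [1, 2, 0]


def test_ties_break_by_ascending_index():
    assert rank_patches(np.array([0.3, 0.3, 0.3])).tolist() == [0, 1, 2]
    assert rank_patches(np.array([0.1, 0.5, 0.5, 0.0])).tolist() == [1, 2, 0, 3]


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
def test_rank_agrees_with_stable_sort_oracle(scores):
    scores = np.asarray(scores)
    want = sorted(range(scores.size), key=lambda i: (-scores[i], i))
    assert rank_patches(scores).tolist() == want


def test_nan_scores_rejected():
    with pytest.raises(InputError):
        rank_patches(np.array([0.1, np.nan]))


# -- curves -------------------------------------------------------------


def test_linear_ramp_insertion_auc_is_half():
    d = 4
    adapter = MaskFunctionAdapter(lambda m: 0.25 * m.sum(), d)
    curve = insertion_curve(adapter, toy_image(d), 1, np.arange(d))
    np.testing.assert_allclose(curve.values, [0, 0.25, 0.5, 0.75, 1.0])
    assert curve.auc == pytest.approx(0.5, abs=1e-15)


def indicator_adapter(d=4):
    return MaskFunctionAdapter(lambda m: 0.25 if m[0] == 1 else 0.0, d)


def test_indicator_insertion_first_and_last():
    d = 4
    im = toy_image(d)
    first = insertion_curve(indicator_adapter(), im, 1, np.array([0, 1, 2, 3]))
    np.testing.assert_allclose(first.values, [0, 0.25, 0.25, 0.25, 0.25])
    assert first.auc == pytest.approx(0.21875, abs=1e-12)
    last = insertion_curve(indicator_adapter(), im, 1, np.array([1, 2, 3, 0]))
    assert last.auc == pytest.approx(0.03125, abs=1e-12)


def test_indicator_deletion_first():
    curve = deletion_curve(indicator_adapter(), toy_image(4), 1, np.array([0, 1, 2, 3]))
    np.testing.assert_allclose(curve.values, [0.25, 0, 0, 0, 0])
    assert curve.auc == pytest.approx(0.03125, abs=1e-12)


def test_constant_classifier_flat_deletion():
    d = 4
    adapter = MaskFunctionAdapter(lambda m: 0.6, d)
    curve = deletion_curve(adapter, toy_image(d), 1, np.arange(d))
    assert curve.auc == pytest.approx(0.6, abs=1e-15)


def test_deletion_is_reversed_insertion_for_set_functions(rng):
    """For f depending only on the present set, deleting top-first visits
    the same coalitions as inserting under the reversed ranking, so the
    deletion curve is that insertion curve read backwards."""
    d = 6
    tbl = rng.random(2**d)
    powers = 1 << np.arange(d)
    adapter = MaskFunctionAdapter(lambda m: tbl[(m * powers).sum()], d)
    ranking = rng.permutation(d)
    ins = insertion_curve(adapter, toy_image(d), 1, ranking[::-1])
    dele = deletion_curve(adapter, toy_image(d), 1, ranking)
    np.testing.assert_array_equal(dele.values, ins.values[::-1])


def test_curve_endpoint_identities_bitwise(image8, linear_sigmoid8, rng):
    ranking = rng.permutation(image8.d)
    ins = insertion_curve(linear_sigmoid8, image8, 1, ranking)
    dele = deletion_curve(linear_sigmoid8, image8, 1, ranking)
    assert ins.values[0] == dele.values[-1]  # fully masked
    assert ins.values[-1] == dele.values[0]  # full image


def test_invalid_permutation_rejected(image8, linear_sigmoid8):
    with pytest.raises(InputError):
        insertion_curve(linear_sigmoid8, image8, 1, np.zeros(image8.d, dtype=int))


def test_ground_truth_ranking_dominates_random(image8, rng):
    """Rearrangement: the true weight order maximises insertion AUC and
    minimises deletion AUC over 200 random rankings, strictly."""
    w = rng.uniform(-1, 1, image8.d)
    adapter = make_linear_patch_scorer(w, link="sigmoid")
    truth_rank = rank_patches(w * image8.patch_mean_intensities())
    best_ins = insertion_curve(adapter, image8, 1, truth_rank).auc
    best_del = deletion_curve(adapter, image8, 1, truth_rank).auc
    for _ in range(200):
        r = rng.permutation(image8.d)
        if np.array_equal(r, truth_rank):
            continue
        assert insertion_curve(adapter, image8, 1, r).auc < best_ins
        assert deletion_curve(adapter, image8, 1, r).auc > best_del


# -- random baseline ----------------------------------------------------


def test_random_baseline_constant_classifier():
    d = 5
    adapter = MaskFunctionAdapter(lambda m: 0.42, d)
    ins, dele = random_baseline(adapter, toy_image(d), 1, n_repeats=5, seed=0)
    assert ins == pytest.approx(0.42, abs=1e-12)
    assert dele == pytest.approx(0.42, abs=1e-12)


def test_random_baseline_symmetric_additive_f_balanced():
    """Equal-weight additive f gives the k/d ramp for every ranking, so
    insertion and deletion means coincide at exactly 1/2."""
    d = 6
    adapter = MaskFunctionAdapter(lambda m: m.sum() / d, d)
    ins, dele = random_baseline(adapter, toy_image(d), 1, n_repeats=10, seed=1)
    assert ins == pytest.approx(0.5, abs=1e-12)
    assert dele == pytest.approx(0.5, abs=1e-12)


def test_random_baseline_indicator_closed_form():
    """With one key patch, the insertion AUC averaged over its uniform rank
    position is the mean of the d+1 possible step-curve areas."""
    d = 4
    im = toy_image(d)
    positions = [
        insertion_curve(indicator_adapter(), im, 1, np.roll(np.arange(d), -k)).auc
        for k in range(d)
    ]
    want = np.mean(positions)
    ins, _ = random_baseline(indicator_adapter(), im, 1, n_repeats=400, seed=2)
    se = np.std(positions) / np.sqrt(400)
    assert abs(ins - want) < 4 * se


def test_random_baseline_reproducible(image8, linear_sigmoid8):
    a = random_baseline(linear_sigmoid8, image8, 1, n_repeats=3, seed=7)
    assert a == random_baseline(linear_sigmoid8, image8, 1, n_repeats=3, seed=7)


# -- aggregation --------------------------------------------------------


def test_aggregate_modes_hand_example():
    data = [("A", 0.2), ("A", 0.4), ("B", 0.9)]
    assert aggregate(data, "per_patch") == pytest.approx(0.5)
    # slide means are 0.3 and 0.9; slides weighted equally
    assert aggregate(data, "per_slide") == pytest.approx(0.6)


def test_single_slide_modes_agree(rng):
    data = [("S", float(x)) for x in rng.random(5)]
    assert aggregate(data, "per_patch") == pytest.approx(aggregate(data, "per_slide"))


def test_balanced_slides_modes_agree(rng):
    data = [(s, float(x)) for s in "AB" for x in rng.random(3)]
    assert aggregate(data, "per_patch") == pytest.approx(aggregate(data, "per_slide"))


def test_empty_aggregate_rejected():
    with pytest.raises(InputError):
        aggregate([], "per_patch")


# -- Welch --------------------------------------------------------------


def _welch_by_hand(a, b):
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return 2 * stdtr(df, -abs(t))


def test_identical_populations_p_one(rng):
    x = rng.normal(size=10)
    mat = welch_t_matrix({"a": x, "b": x.copy()})
    assert mat.loc["a", "b"] == pytest.approx(1.0)


def test_welch_matches_textbook_computation(rng):
    a = rng.normal(0.0, 1.0, 12)
    b = rng.normal(0.5, 2.0, 7)
    mat = welch_t_matrix({"a": a, "b": b})
    assert mat.loc["a", "b"] == pytest.approx(_welch_by_hand(a, b), abs=1e-6)
    assert mat.loc["b", "a"] == mat.loc["a", "b"]  # symmetry
    assert np.isnan(mat.loc["a", "a"])


def test_degenerate_variance_handling():
    same = welch_t_matrix({"a": np.full(3, 0.5), "b": np.full(4, 0.5)})
    assert same.loc["a", "b"] == 1.0
    diff = welch_t_matrix({"a": np.full(3, 0.5), "b": np.full(4, 0.9)})
    assert diff.loc["a", "b"] == 0.0


def test_small_population_rejected():
    with pytest.raises(InputError):
        welch_t_matrix({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


# -- top-k precision ----------------------------------------------------


def test_top_k_precision_basics():
    scores = np.array([0.9, 0.1, 0.8, 0.2])
    assert top_k_precision(scores, np.array([0, 2])) == 1.0
    assert top_k_precision(scores, np.array([1, 3])) == 0.0
    assert top_k_precision(scores, np.array([0, 1])) == 0.5


def test_attribution_map_ranking_roundtrip(rng):
    amap = AttributionMap(rng.normal(size=6), method="x")
    np.testing.assert_array_equal(amap.ranking(), rank_patches(amap.scores))
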