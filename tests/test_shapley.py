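"""Shapley estimators, kernels, mask laws and the toy explainer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchexplain.errors import InputError, SizeError, SolverError
from patchexplain.models import MaskFunctionAdapter
from patchexplain.rise import enumerate_masks
from patchexplain.shapley import (
    CooperativeGame,
    ExplainerModel,
    ExplainerTrainConfig,
    additive_efficient_normalization,
    exact_shapley,
    make_image_game,
    random_additive_games,
    regression_shapley,
    sample_surrogate_masks,
    shapley_kernel,
    singleton_features,
    surrogate_mask_law,
    surrogate_objective,
    train_explainer,
)
from patchexplain.synthetic import make_linear_patch_scorer
from scipy import stats


def table_game(rng, d, name="table"):
    """Random set function with v(0) = 0, stored as a 2^d lookup table."""
    tbl = rng.normal(size=2**d)
    tbl[0] = 0.0
    powers = 1 << np.arange(d)
    return CooperativeGame(
        d, lambda masks, tbl=tbl: tbl[(np.asarray(masks) * powers).sum(axis=1)], name
    )


# -- exact enumeration --------------------------------------------------


def test_two_player_hand_enumeration():
    game = CooperativeGame.from_function(
        lambda m: {(0, 0): 0.0, (1, 0): 1.0, (0, 1): 2.0, (1, 1): 4.0}[tuple(m)], 2
    )
    res = exact_shapley(game)
    np.testing.assert_allclose(res.phi, [1.5, 2.5])
    assert res.grand_value == 4.0


def test_symmetric_game_equal_values(rng):
    d = 5
    game = CooperativeGame.from_function(lambda m: float(m.sum()) ** 1.5, d)
    phi = exact_shapley(game).phi
    np.testing.assert_allclose(phi, phi[0])


def test_dummy_player_gets_zero(rng):
    d = 4
    game = CooperativeGame.from_function(lambda m: float(m[0] + 2 * m[2]), d)
    phi = exact_shapley(game).phi
    assert phi[1] == pytest.approx(0.0, abs=1e-12)
    assert phi[3] == pytest.approx(0.0, abs=1e-12)


def test_efficiency_exact(rng):
    game = table_game(rng, 6)
    res = exact_shapley(game)
    assert res.efficiency_gap() < 1e-9


def test_linearity_of_exact_values(rng):
    d = 5
    g1, g2 = table_game(rng, d), table_game(rng, d)
    gsum = CooperativeGame(
        d, lambda m: g1.evaluate_batch(m) + g2.evaluate_batch(m)
    )
    np.testing.assert_allclose(
        exact_shapley(gsum).phi,
        exact_shapley(g1).phi + exact_shapley(g2).phi,
        atol=1e-10,
    )


def test_enumeration_guard():
    game = CooperativeGame.from_function(lambda m: float(m.sum()), 15)
    with pytest.raises(SizeError):
        exact_shapley(game)


def test_baseline_violation_detected():
    game = CooperativeGame.from_function(lambda m: 1.0, 3)
    with pytest.raises(InputError):
        exact_shapley(game)


# -- kernel and mask laws ----------------------------------------------


def test_shapley_kernel_d3_uniform_over_admissible_masks():
    kw = shapley_kernel(3)
    np.testing.assert_allclose(kw.per_mask, [0, 1 / 6, 1 / 6, 0])
    assert kw.total_mass() == pytest.approx(1.0)


def test_shapley_kernel_d4_cardinality_ratio():
    kw = shapley_kernel(4)
    # per-mask weight ratio |m|=2 vs |m|=1 is (1!1!)/(0!2!) = 1/2
    assert kw.per_mask[2] / kw.per_mask[1] == pytest.approx(0.5)
    assert kw.per_mask[0] == 0.0 and kw.per_mask[4] == 0.0


@pytest.mark.parametrize("d", [2, 5, 8, 12])
def test_mask_laws_sum_to_one_by_enumeration(d):
    for kw in (shapley_kernel(d), surrogate_mask_law(d)):
        masks = enumerate_masks(d)
        assert kw.mask_probability(masks).sum() == pytest.approx(1.0, abs=1e-12)


def test_surrogate_law_d2_values():
    kw = surrogate_mask_law(2)
    # p(00) = p(11) = 1/3, p(10) = p(01) = 1/6
    np.testing.assert_allclose(kw.per_mask, [1 / 3, 1 / 6, 1 / 3])


def test_surrogate_sampler_cardinality_uniform():
    batch = sample_surrogate_masks(20000, 8, seed=0)
    counts = np.bincount(batch.masks.sum(axis=1), minlength=9)
    assert stats.chisquare(counts).pvalue > 0.001


def test_kernel_needs_two_players():
    with pytest.raises(InputError):
        shapley_kernel(1)


# -- regression estimator -----------------------------------------------


def test_additive_game_recovered_exactly(rng):
    w = rng.normal(size=6)
    game = CooperativeGame.additive(w)
    res = regression_shapley(game, exhaustive=True)
    np.testing.assert_allclose(res.phi, w, atol=1e-9)


def test_exhaustive_regression_matches_enumeration(rng):
    for _ in range(5):
        game = table_game(rng, 8)
        ex = exact_shapley(game)
        reg = regression_shapley(game, exhaustive=True)
        assert np.abs(ex.phi - reg.phi).max() < 1e-6
        assert reg.efficiency_gap() < 1e-6


def test_sampled_regression_within_bootstrap_error(rng):
    """Kernel-sampled estimate agrees with enumeration within 3 bootstrap SEs."""
    game = table_game(rng, 8, "sampled")
    exact = exact_shapley(game).phi
    n = 20000
    batch = shapley_kernel(8).sample(n, seed=9)
    est = regression_shapley(game, masks=batch).phi
    boot = np.empty((40, 8))
    for b in range(40):
        idx = rng.integers(0, n, n)
        boot[b] = regression_shapley(game, masks=batch.masks[idx]).phi
    se = boot.std(axis=0, ddof=1)
    assert (np.abs(est - exact) < 3 * se + 1e-9).all()


def test_rank_deficient_design_raises():
    game = CooperativeGame.additive(np.ones(5))
    same = np.tile(np.array([[1, 0, 0, 0, 0]]), (10, 1))
    with pytest.raises(SolverError):
        regression_shapley(game, masks=same)


def test_too_few_masks_raises():
    game = CooperativeGame.additive(np.ones(5))
    with pytest.raises(SolverError):
        regression_shapley(game, masks=np.array([[1, 0, 0, 0, 0]]))


# -- normalisation ------------------------------------------------------


def test_normalization_forced_example():
    np.testing.assert_allclose(
        additive_efficient_normalization(np.array([1.0, 1.0]), 4.0), [2.0, 2.0]
    )


@settings(derandomize=True, max_examples=30)
@given(
    phi=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    v1=st.floats(-5, 5),
)
def test_normalization_efficient_and_idempotent(phi, v1):
    phi = np.asarray(phi)
    once = additive_efficient_normalization(phi, v1)
    assert once.sum() == pytest.approx(v1, abs=1e-9)
    np.testing.assert_allclose(
        additive_efficient_normalization(once, v1), once, atol=1e-12
    )


def test_already_efficient_unchanged():
    phi = np.array([0.25, 0.75])
    np.testing.assert_array_equal(additive_efficient_normalization(phi, 1.0), phi)


# -- image games --------------------------------------------------------


def test_image_game_baseline_is_zero(image8, linear_sigmoid8):
    game = make_image_game(linear_sigmoid8, image8, 1)
    assert game.evaluate(np.zeros(image8.d, dtype=np.int8)) == 0.0
    full = linear_sigmoid8.predict_proba(image8)[1]
    assert game.grand_value() == pytest.approx(full - game.baseline_prediction)


def test_constant_classifier_game_identically_zero(image8):
    adapter = MaskFunctionAdapter(lambda m: 0.4, image8.d)
    game = make_image_game(adapter, image8, 1)
    np.testing.assert_allclose(exact_shapley(game).phi, 0.0, atol=1e-12)


def test_invalid_class_rejected(image8, linear_sigmoid8):
    with pytest.raises(InputError):
        make_image_game(linear_sigmoid8, image8, 5)


# -- surrogate objective ------------------------------------------------


def test_kl_zero_iff_equal(rng):
    p = rng.dirichlet(np.ones(4))
    assert surrogate_objective(p, p) == pytest.approx(0.0, abs=1e-12)
    for _ in range(5):
        q = rng.dirichlet(np.ones(4))
        assert surrogate_objective(p, q) >= 0.0


def test_kl_closed_form():
    assert surrogate_objective([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))


def test_kl_rejects_unnormalised():
    with pytest.raises(InputError):
        surrogate_objective([0.9, 0.3], [0.5, 0.5])


# -- toy explainer ------------------------------------------------------


def test_explainer_forward_is_efficient_by_construction(rng):
    model = ExplainerModel(6, seed=0)
    phi = model.forward(rng.normal(size=6), grand_value=0.77)
    assert abs(phi.sum() - 0.77) < 1e-6


def test_explainer_training_reduces_loss_and_recovers_additive_games():
    train = random_additive_games(24, 6, seed=0)
    held_out = random_additive_games(8, 6, seed=100)
    model = ExplainerModel(6, seed=1)
    init_losses = []
    for g in held_out:
        phi = model.forward(singleton_features(g), g.grand_value())
        init_losses.append(np.abs(phi - g.contributions).mean())
    model, trace = train_explainer(
        train, model, config=ExplainerTrainConfig(epochs=60, seed=2)
    )
    assert trace[-1] < trace[0]
    errs, ranges = [], []
    for g in held_out:
        phi = model.forward(singleton_features(g), g.grand_value())
        assert abs(phi.sum() - g.grand_value()) < 1e-6
        errs.append(np.abs(phi - g.contributions).mean())
        ranges.append(np.ptp(g.contributions))
    assert np.mean(errs) < 0.05 * np.mean(ranges)
    assert np.mean(errs) < np.mean(init_losses)
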