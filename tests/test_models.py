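"""Adapter contract: probabilities, masking, attention, gradients."""

import numpy as np
import pytest

from patchexplain import (
    PatchedImage,
    attention_maps,
    gradient,
    masked_predict,
    predict,
)
from patchexplain.errors import CapabilityError, InputError
from patchexplain.models import AttentionStack, MaskFunctionAdapter
from patchexplain.synthetic import make_linear_patch_scorer, make_tiny_vit


def test_zero_weight_sigmoid_scorer_is_uniform_on_any_image(image8):
    adapter = make_linear_patch_scorer(np.zeros(image8.d), link="sigmoid")
    np.testing.assert_allclose(predict(adapter, image8)[0], [0.5, 0.5])


@pytest.mark.parametrize("model", ["linear", "vit"])
def test_probabilities_normalised(model, image8, linear_sigmoid8, tiny_vit16, vit_image16):
    adapter, image = (
        (linear_sigmoid8, image8) if model == "linear" else (tiny_vit16, vit_image16)
    )
    p = predict(adapter, [image, image])
    assert p.shape == (2, adapter.n_classes)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert (p >= 0).all()


def test_tiny_vit_deterministic_across_calls(tiny_vit16, vit_image16):
    p1 = tiny_vit16.predict_proba(vit_image16)
    p2 = tiny_vit16.predict_proba(vit_image16)
    np.testing.assert_array_equal(p1, p2)


def test_same_seed_same_model(vit_image16):
    a = make_tiny_vit(2, 2, 16, seed=9)
    b = make_tiny_vit(2, 2, 16, seed=9)
    np.testing.assert_array_equal(
        a.predict_proba(vit_image16), b.predict_proba(vit_image16)
    )
    assert not np.array_equal(
        a.predict_proba(vit_image16),
        make_tiny_vit(2, 2, 16, seed=10).predict_proba(vit_image16),
    )


def test_batch_predict_rejects_mixed_shapes(linear_sigmoid8, image8):
    other = PatchedImage(np.zeros((8, 8, 3)), 8)
    with pytest.raises(InputError):
        predict(linear_sigmoid8, [image8, other])


@pytest.mark.parametrize("model", ["linear", "vit"])
def test_all_ones_mask_is_bit_identical_to_predict(
    model, image8, linear_sigmoid8, tiny_vit16, vit_image16
):
    adapter, image = (
        (linear_sigmoid8, image8) if model == "linear" else (tiny_vit16, vit_image16)
    )
    ones = np.ones(image.d, dtype=np.int8)
    np.testing.assert_array_equal(
        masked_predict(adapter, image, ones), adapter.predict_proba(image)
    )


def test_all_zeros_mask_is_black_image_baseline(linear_sigmoid8, image8):
    zeros = np.zeros(image8.d, dtype=np.int8)
    black = PatchedImage(np.zeros_like(image8.pixels), image8.patch_size)
    np.testing.assert_array_equal(
        masked_predict(linear_sigmoid8, image8, zeros, fill=0.0),
        linear_sigmoid8.predict_proba(black),
    )


def test_linear_masked_logit_is_sum_of_included_contributions(image8, rng):
    w = rng.normal(size=image8.d)
    adapter = make_linear_patch_scorer(w, bias=0.3)
    mu = image8.patch_mean_intensities()
    mask = rng.integers(0, 2, image8.d).astype(np.int8)
    got = adapter.masked_predict(image8, mask)[1]
    want = (w * mu)[mask == 1].sum() + 0.3
    assert got == pytest.approx(want, abs=1e-12)


def test_mask_length_mismatch_raises(linear_sigmoid8, image8):
    with pytest.raises(InputError):
        masked_predict(linear_sigmoid8, image8, np.ones(image8.d + 1, dtype=np.int8))


# -- attention ----------------------------------------------------------


def test_vit_attention_rows_stochastic_and_shape(tiny_vit16, vit_image16):
    stack = attention_maps(tiny_vit16, vit_image16)
    assert stack.layers.shape == (2, 17, 17)
    np.testing.assert_allclose(stack.layers.sum(axis=2), 1.0, atol=1e-5)
    assert (stack.layers >= 0).all()


def test_four_layer_vit_stack_shape(vit_image16):
    vit = make_tiny_vit(layers=4, heads=2, d=16, seed=2)
    assert attention_maps(vit, vit_image16).layers.shape == (4, 17, 17)


def test_identical_heads_average_to_either_head():
    row = np.full((3, 3), 1 / 3)
    both = np.stack([row, row])  # two identical heads
    np.testing.assert_array_equal(both.mean(axis=0), row)
    AttentionStack(row[None])  # and the average is a valid stack


def test_attention_capability_error(linear_identity8, image8):
    with pytest.raises(CapabilityError):
        attention_maps(linear_identity8, image8)


def test_non_stochastic_stack_rejected():
    with pytest.raises(InputError):
        AttentionStack(np.ones((1, 3, 3)))


# -- gradients ----------------------------------------------------------


def test_linear_gradient_is_weight_per_pixel(image8, rng):
    w = rng.normal(size=image8.d)
    adapter = make_linear_patch_scorer(w)
    g = gradient(adapter, image8, 1)
    n = image8.patch_size**2 * 3
    for i in range(image8.d):
        rs, cs = image8.patch_slices(i)
        np.testing.assert_allclose(g[rs, cs, :], w[i] / n)
    np.testing.assert_array_equal(gradient(adapter, image8, 0), -g)


def test_constant_classifier_zero_gradient(image8):
    adapter = make_linear_patch_scorer(np.zeros(image8.d))
    assert not gradient(adapter, image8, 1).any()


@pytest.mark.parametrize("target", ["logit", "probability"])
def test_vit_gradient_matches_finite_differences(target, tiny_vit16, vit_image16):
    """Central differences (h=1e-4) at 10 random pixels, 1e-3 relative."""
    g = gradient(tiny_vit16, vit_image16, 1, target=target)
    rng = np.random.default_rng(0)
    h = 1e-4
    for _ in range(10):
        i, j, k = (
            int(rng.integers(vit_image16.pixels.shape[0])),
            int(rng.integers(vit_image16.pixels.shape[1])),
            int(rng.integers(3)),
        )
        hi = vit_image16.pixels.copy()
        lo = vit_image16.pixels.copy()
        hi[i, j, k] += h
        lo[i, j, k] -= h
        fd = (
            tiny_vit16.target_value(PatchedImage(hi, 8), 1, target)
            - tiny_vit16.target_value(PatchedImage(lo, 8), 1, target)
        ) / (2 * h)
        assert g[i, j, k] == pytest.approx(fd, rel=1e-3, abs=1e-8)


def test_invalid_class_index_raises(tiny_vit16, vit_image16):
    with pytest.raises(InputError):
        gradient(tiny_vit16, vit_image16, 7)


def test_gradient_capability_error(image8):
    adapter = MaskFunctionAdapter(lambda m: 0.5, image8.d)
    with pytest.raises(CapabilityError):
        gradient(adapter, image8, 1)


# -- PatchedImage geometry ---------------------------------------------


def test_patch_indexing_row_major():
    px = np.arange(4 * 6 * 3, dtype=float).reshape(4, 6, 3) / 300
    im = PatchedImage(px, 2)
    assert im.grid == (2, 3)
    assert im.d == 6
    # patch 4 -> grid cell (1, 1)
    rs, cs = im.patch_slices(4)
    assert (rs.start, rs.stop, cs.start, cs.stop) == (2, 4, 2, 4)
    np.testing.assert_array_equal(im.patch_array()[4], px[2:4, 2:4])


def test_indivisible_image_rejected():
    with pytest.raises(InputError):
        PatchedImage(np.zeros((10, 8, 3)), 3)
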