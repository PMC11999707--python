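import numpy as np
import pytest

from patchexplain import PatchedImage
from patchexplain.synthetic import (
    SyntheticSlideSpec,
    generate_pseudo_slide,
    make_linear_patch_scorer,
    make_tiny_vit,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def slide8():
    """Zero-noise 2x4 pseudo-slide (d=8) with two planted tumor patches."""
    spec = SyntheticSlideSpec(
        grid=(2, 4),
        patch_size=8,
        tumor_patches=frozenset({1, 6}),
        background_patches=frozenset({3}),
        noise_scale=0.0,
        seed=5,
    )
    return generate_pseudo_slide(spec)


@pytest.fixture
def image8(slide8):
    return slide8[0]


@pytest.fixture
def linear_identity8(image8, rng):
    """Identity-link scorer with small positive weights (probabilities stay in [0, 1])."""
    return make_linear_patch_scorer(rng.uniform(0.02, 0.1, image8.d))


@pytest.fixture
def linear_sigmoid8(image8, rng):
    return make_linear_patch_scorer(rng.uniform(-0.5, 0.5, image8.d), link="sigmoid")


@pytest.fixture(scope="session")
def tiny_vit16():
    return make_tiny_vit(layers=2, heads=2, d=16, seed=1)


@pytest.fixture(scope="session")
def vit_image16():
    spec = SyntheticSlideSpec(
        grid=(4, 4), patch_size=8, tumor_patches=frozenset({0, 5}), seed=7
    )
    return generate_pseudo_slide(spec)[0]


@pytest.fixture
def black_image16(vit_image16):
    return PatchedImage(np.zeros_like(vit_image16.pixels), vit_image16.patch_size)
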