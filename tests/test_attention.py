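import numpy as np
import pytest

from snetseg.attention import (CBAMBlock, apply_cbam, channel_attention,
                               spatial_attention)
from snetseg.nn import Tensor


@pytest.fixture
def block(rng):
    return CBAMBlock(channels=8, reduction=2, rng=rng)


def test_channel_weights_sum_to_one(block, rng):
    F = rng.normal(size=(8, 6, 6))
    w = channel_attention(F, block).weights
    assert w.shape == (8,)
    assert w.sum() == pytest.approx(1.0, abs=1e-6)
    assert (w >= 0).all()


def test_channel_weights_uniform_on_channel_constant_input(rng):
    # all channels identical: no channel can be preferred
    blk = CBAMBlock(channels=4, reduction=1, identity_init=True)
    F = np.broadcast_to(rng.normal(size=(1, 5, 5)), (4, 5, 5)).copy()
    w = channel_attention(F, blk).weights
    np.testing.assert_allclose(w, 0.25, atol=1e-6)


def test_spatial_weights_sum_and_uniformity(block, rng):
    F = rng.normal(size=(8, 4, 4))
    w = spatial_attention(F, block).weights
    assert w.shape == (4, 4)
    assert w.sum() == pytest.approx(1.0, abs=1e-6)
    const = np.ones((8, 4, 4)) * 2.5
    wu = spatial_attention(const, block).weights
    np.testing.assert_allclose(wu, 1.0 / 16, atol=1e-6)


def test_apply_cbam_uniform_weights_is_identity(rng):
    # constant input yields uniform channel and spatial weights; with
    # rescaling the refinement is then exactly the identity
    blk = CBAMBlock(channels=4, reduction=1, identity_init=True, rescale=True)
    F = np.full((4, 6, 6), 1.7)
    out = apply_cbam(F, blk)
    np.testing.assert_allclose(out, F, rtol=1e-5)


def test_channel_permutation_equivariance(block, rng):
    F = rng.normal(size=(8, 5, 5))
    perm = rng.permutation(8)
    w = channel_attention(F, block).weights
    w_perm = channel_attention(F[perm], block.permute_channels(perm)).weights
    np.testing.assert_allclose(w_perm, w[perm], rtol=1e-5, atol=1e-7)


def test_forward_preserves_shape_and_grads(block, rng):
    x = Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32),
               requires_grad=True)
    out = block(x)
    assert out.data.shape == x.data.shape
    out.sum().backward()
    assert np.abs(x.grad).max() > 0


def test_validation_errors(rng):
    with pytest.raises(ValueError):
        CBAMBlock(channels=8, reduction=3)
    with pytest.raises(ValueError):
        CBAMBlock(channels=8, activation="tanh")
    blk = CBAMBlock(channels=8, reduction=2)
    with pytest.raises(ValueError):
        channel_attention(rng.normal(size=(4, 4, 4)), blk)


def test_sigmoid_variant(rng):
    blk = CBAMBlock(channels=4, reduction=2, activation="sigmoid", rng=rng)
    F = rng.normal(size=(4, 4, 4))
    w = channel_attention(F, blk).weights
    assert ((w > 0) & (w < 1)).all()
    out = apply_cbam(F, blk)
    assert out.shape == F.shape
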