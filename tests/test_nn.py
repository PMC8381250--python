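"""Numerical gradient checks for the autodiff layer primitives."""

import numpy as np
import pytest

from snetseg.nn import Tensor, concat, conv2d, maxpool2, softmax, upsample2
from snetseg.nn.autograd import batchnorm2d, no_grad


def _num_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def _check(build, *arrays, tol=1e-5):
    """build(*tensors) -> scalar Tensor; compares backward vs numeric."""
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    out.backward()
    for t, a in zip(tensors, arrays):
        num = _num_grad(lambda: float(build(*[Tensor(x) for x in arrays]).data), a)
        np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


def test_conv2d_grad(rng):
    x = rng.normal(size=(2, 2, 5, 5))
    w = rng.normal(size=(3, 2, 3, 3))
    b = rng.normal(size=3)
    _check(lambda x_, w_, b_: (conv2d(x_, w_, b_) ** 2).sum(), x, w, b)


def test_conv2d_matches_direct_convolution(rng):
    from scipy import ndimage
    x = rng.normal(size=(1, 1, 6, 6))
    w = rng.normal(size=(1, 1, 3, 3))
    out = conv2d(Tensor(x), Tensor(w), Tensor(np.zeros(1))).data[0, 0]
    ref = ndimage.correlate(x[0, 0], w[0, 0], mode="constant", cval=0.0)
    np.testing.assert_allclose(out, ref, rtol=1e-6, atol=1e-6)


def test_maxpool_and_upsample_grad(rng):
    x = rng.normal(size=(1, 2, 4, 4))
    _check(lambda x_: (maxpool2(x_) * 1.5).sum(), x)
    _check(lambda x_: (upsample2(x_) ** 2).sum(), x)


def test_batchnorm_grad(rng):
    x = rng.normal(size=(3, 2, 3, 3))
    g = rng.normal(size=(1, 2, 1, 1))
    b = rng.normal(size=(1, 2, 1, 1))

    def build(x_, g_, b_):
        mean = x_.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x_.data.var(axis=(0, 2, 3), keepdims=True)
        y = batchnorm2d(x_, g_, b_, 1e-5, mean, var, batch_stats=True)
        return (y ** 2).sum()

    _check(build, x, g, b, tol=1e-4)


def test_softmax_concat_grad(rng):
    a = rng.normal(size=(2, 3))
    b = rng.normal(size=(2, 3))
    _check(lambda a_, b_: (softmax(concat([a_, b_], axis=1), axis=1) ** 2).sum(),
           a, b)


def test_elementwise_grads(rng):
    x = rng.normal(size=(4, 3))
    _check(lambda x_: x_.sigmoid().sum(), x)
    _check(lambda x_: ((x_ * 2.0 + 1.0) ** 2).mean(), x)
    xp = np.abs(rng.normal(size=(4, 3))) + 0.5
    _check(lambda x_: x_.sqrt().sum(), xp)
    _check(lambda x_: x_.log().sum(), xp)


def test_amax_grad_spreads_ties():
    x = np.array([[1.0, 2.0, 2.0]])
    t = Tensor(x, requires_grad=True)
    t.amax(axis=1).sum().backward()
    # every tied maximizer receives the full upstream gradient
    assert t.grad[0, 0] == 0.0
    assert t.grad[0, 1] == 1.0 and t.grad[0, 2] == 1.0


def test_no_grad_blocks_graph(rng):
    x = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
    with no_grad():
        y = (x * 3.0).sum()
    assert y._parents == ()
    y2 = (x * 3.0).sum()
    y2.backward()
    np.testing.assert_allclose(x.grad, 3.0)


def test_broadcast_add_grad(rng):
    x = rng.normal(size=(2, 3, 4))
    b = rng.normal(size=(1, 3, 1))
    _check(lambda x_, b_: ((x_ + b_) ** 2).sum(), x, b)
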