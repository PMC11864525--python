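"""Gradient and semantics checks for the numpy autodiff/NN engine."""

import numpy as np
import pytest

from uperc3d import nn
from uperc3d.nn import Tensor, functional as F


def numgrad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize("padding,stride,xshape,wshape", [
    ("same", 1, (2, 2, 4, 4, 4), (3, 2, 3, 3, 3)),
    ("valid", 1, (1, 2, 5, 5, 5), (2, 2, 3, 3, 3)),
    (1, 2, (1, 2, 6, 6, 6), (2, 2, 3, 3, 3)),
    (2, 4, (1, 1, 11, 11, 11), (2, 1, 5, 5, 5)),
])
def test_conv3d_gradients_match_finite_differences(padding, stride, xshape, wshape):
    rng = np.random.default_rng(0)
    x = rng.normal(size=xshape)
    w = rng.normal(size=wshape)
    b = rng.normal(size=(wshape[0],))

    def run(xv, wv, bv):
        xt = Tensor(xv.copy(), requires_grad=True)
        wt = Tensor(wv.copy(), requires_grad=True)
        bt = Tensor(bv.copy(), requires_grad=True)
        out = F.conv3d(xt, wt, bt, stride=stride, padding=padding)
        return (out * out).sum() * 0.5, xt, wt, bt

    loss, xt, wt, bt = run(x, w, b)
    loss.backward()
    assert np.allclose(xt.grad, numgrad(lambda v: run(v, w, b)[0].item(), x), atol=1e-5)
    assert np.allclose(wt.grad, numgrad(lambda v: run(x, v, b)[0].item(), w), atol=1e-5)
    assert np.allclose(bt.grad, numgrad(lambda v: run(x, w, v)[0].item(), b), atol=1e-5)


def test_conv3d_matches_scipy_correlate():
    from scipy import ndimage

    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 1, 6, 5, 7))
    w = rng.normal(size=(1, 1, 3, 3, 3))
    out = F.conv3d(Tensor(x), Tensor(w), None, padding="same").numpy()
    ref = ndimage.correlate(x[0, 0], w[0, 0], mode="constant")
    assert np.allclose(out[0, 0], ref, atol=1e-10)


def test_maxpool_gradient_routes_to_argmax():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, 2, 4, 4, 4))
    xt = Tensor(x.copy(), requires_grad=True)
    out = F.max_pool3d(xt, 2, 2)
    assert out.shape == (1, 2, 2, 2, 2)
    out.sum().backward()
    # gradient is 1 exactly at each window argmax, 0 elsewhere
    assert xt.grad.sum() == out.data.size
    assert set(np.unique(xt.grad)) <= {0.0, 1.0}
    assert np.allclose(np.sort(x[xt.grad == 1.0]), np.sort(out.numpy().ravel()))


def test_batchnorm_normalizes_and_tracks_running_stats():
    bn = nn.BatchNorm3d(3)
    rng = np.random.default_rng(3)
    x = rng.normal(loc=2.0, scale=4.0, size=(4, 3, 5, 5, 5)).astype(np.float32)
    out = bn(Tensor(x)).numpy()
    assert np.allclose(out.mean(axis=(0, 2, 3, 4)), 0.0, atol=1e-5)
    assert np.allclose(out.std(axis=(0, 2, 3, 4)), 1.0, atol=1e-3)
    # eval mode uses running averages, not batch stats
    bn.eval()
    shifted = x + 100.0
    out_eval = bn(Tensor(shifted)).numpy()
    assert out_eval.mean() > 10.0


def test_attention_softmax_block_gradcheck():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(2, 4, 6))

    def run(xv):
        xt = Tensor(xv.copy(), requires_grad=True)
        q = F.l2_normalize(xt, axis=-1)
        a = F.softmax((q @ q.transpose((0, 2, 1))) * 2.0, axis=-1)
        return (a * a).sum(), xt

    loss, xt = run(x)
    loss.backward()
    assert np.allclose(xt.grad, numgrad(lambda v: run(v)[0].item(), x), atol=1e-6)


def test_adam_single_step_matches_closed_form():
    p = nn.Parameter(np.array([1.0, -2.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.1)
    p.grad = np.array([0.5, -1.0], dtype=np.float32)
    opt.step()
    # first step: m_hat = g, v_hat = g^2  =>  update = -lr * g/(|g|+eps) = -lr*sign(g)
    assert np.allclose(p.data, [1.0 - 0.1, -2.0 + 0.1], atol=1e-6)


def test_state_dict_round_trip_restores_weights_and_buffers():
    from uperc3d import DenoiserConfig, build_denoiser

    m1 = build_denoiser(DenoiserConfig(architecture="resnet", resnet_channels=4,
                                       resnet_blocks=2), seed=0)
    m2 = build_denoiser(DenoiserConfig(architecture="resnet", resnet_channels=4,
                                       resnet_blocks=2), seed=1)
    state = m1.state_dict()
    assert any(k.endswith("running_mean") for k in state)
    m2.load_state_dict(state)
    for k, v in m2.state_dict().items():
        assert np.array_equal(v, state[k]), k


def test_frozen_parameters_receive_no_gradient():
    conv = nn.Conv3d(1, 2, 3, rng=np.random.default_rng(0))
    conv.freeze()
    x = Tensor(np.random.default_rng(1).normal(size=(1, 1, 4, 4, 4)), requires_grad=True)
    (conv(x) ** 2).sum().backward()
    assert conv.weight.grad is None and conv.bias.grad is None
    assert x.grad is not None and np.abs(x.grad).max() > 0
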