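"""Backbone architecture contracts: shapes, ablation switches, attention math."""

import numpy as np
import pytest

import uamt3d.autograd as ag
from uamt3d.autograd import Tensor
from uamt3d.backbone import NetworkSpec, build_network
from uamt3d.errors import ConfigurationError
from uamt3d.layers import CBAM, ChannelAttention, SpatialAttention


def test_forward_preserves_spatial_shape_and_sets_classes(tiny_net, rng):
    x = rng.standard_normal((1, 32, 32, 16)).astype(np.float32)
    out = tiny_net.forward(x)
    assert out.shape == (2, 32, 32, 16)
    assert np.isfinite(out.data).all()


@pytest.mark.parametrize("use_residual,use_cbam,expect_cbam,expect_shortcut", [
    (False, False, False, False),
    (True, False, False, True),
    (True, True, True, True),
])
def test_ablation_flags_control_parameter_structure(use_residual, use_cbam,
                                                    expect_cbam, expect_shortcut):
    spec = NetworkSpec(levels=2, base_channels=2, use_residual=use_residual,
                       use_cbam=use_cbam, sam_kernel=3)
    names = build_network(spec).parameters().keys()
    assert any("cbam" in n for n in names) == expect_cbam
    assert any("shortcut" in n for n in names) == expect_shortcut


def test_ablation_flags_change_parameter_count():
    base = NetworkSpec(levels=2, base_channels=2, sam_kernel=3)
    n_plain = sum(p.data.size for p in build_network(
        NetworkSpec(levels=2, base_channels=2, use_residual=False,
                    use_cbam=False)).parameters().values())
    n_full = sum(p.data.size for p in build_network(base).parameters().values())
    assert n_full > n_plain


def test_deterministic_eval_stochastic_train(tiny_net, rng):
    x = rng.standard_normal((1, 16, 16, 8)).astype(np.float32)
    a = tiny_net.forward(x).data
    b = tiny_net.forward(x).data
    np.testing.assert_array_equal(a, b)
    r = np.random.default_rng(0)
    c = tiny_net.forward(x, training=True, rng=r).data
    d = tiny_net.forward(x, training=True, rng=r).data
    assert not np.array_equal(c, d)


def test_too_deep_network_rejected():
    spec = NetworkSpec(levels=4, base_channels=2)
    net = build_network(spec)
    with pytest.raises(ConfigurationError):
        net.forward(np.zeros((1, 8, 8, 8), dtype=np.float32))


def test_channel_attention_weights_in_unit_interval(rng):
    cam = ChannelAttention(4, reduction=2, rng=rng)
    w = cam.weights(Tensor(rng.standard_normal((4, 6, 6, 6)))).data
    assert w.shape == (4,)
    assert ((w > 0) & (w < 1)).all()


def test_channel_attention_branches_coincide_on_constant_map(rng):
    cam = ChannelAttention(3, reduction=1, rng=rng)
    x = np.ones((3, 4, 4, 4)) * np.array([1.0, -2.0, 0.5])[:, None, None, None]
    # constant spatial map: max-pool == avg-pool, so the gate equals
    # sigmoid(2 * MLP(descriptor))
    v = x[:, 0, 0, 0][None]
    mlp = np.maximum(v @ cam.w1.data, 0.0) @ cam.w2.data
    expected = 1.0 / (1.0 + np.exp(-2.0 * mlp[0]))
    np.testing.assert_allclose(cam.weights(Tensor(x)).data, expected, rtol=1e-5)


def test_channel_attention_matches_hand_computation():
    cam = ChannelAttention(2, reduction=1, rng=np.random.default_rng(0))
    cam.w1.data = np.array([[1.0, -1.0], [0.5, 2.0]], dtype=np.float32)
    cam.w2.data = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=np.float32)
    x = np.zeros((2, 2, 2, 2), dtype=np.float32)
    x[0], x[1] = 1.0, 2.0
    x[0, 0, 0, 0], x[1, 1, 1, 1] = 3.0, 4.0
    vmax = np.array([3.0, 4.0])
    vavg = np.array([x[0].mean(), x[1].mean()])

    def mlp(v):
        return np.maximum(v @ cam.w1.data, 0) @ cam.w2.data

    expected = 1.0 / (1.0 + np.exp(-(mlp(vmax) + mlp(vavg))))
    np.testing.assert_allclose(cam.weights(Tensor(x)).data, expected, rtol=1e-5)


def test_channel_attention_rejects_oversized_reduction(rng):
    with pytest.raises(ConfigurationError):
        ChannelAttention(2, reduction=4, rng=rng)


def test_spatial_attention_shape_range_and_hand_value(rng):
    sam = SpatialAttention(3, rng=rng)
    x = Tensor(np.full((1, 4, 4, 4), 2.0, dtype=np.float32))
    w = sam.weights(x).data
    assert w.shape == (1, 4, 4, 4)
    assert ((w > 0) & (w < 1)).all()
    # constant input: max and mean maps are both 2, so the pre-sigmoid map is
    # a correlation of the constant 2-channel stack with the conv kernel
    from scipy import ndimage
    k = sam.conv.weight.data
    lin = (ndimage.correlate(np.full((4, 4, 4), 2.0), k[0, 0], mode="constant")
           + ndimage.correlate(np.full((4, 4, 4), 2.0), k[0, 1], mode="constant")
           + sam.conv.bias.data[0])
    np.testing.assert_allclose(w[0], 1 / (1 + np.exp(-lin)), rtol=1e-4)


def test_spatial_attention_rejects_even_kernel(rng):
    with pytest.raises(ConfigurationError):
        SpatialAttention(4, rng=rng)


def test_cbam_is_channel_then_spatial(rng):
    """Serial order: output equals sam(cam(x)) exactly, not cam(sam(x))."""
    cbam = CBAM(3, reduction=1, kernel=3, rng=rng)
    x = Tensor(rng.standard_normal((3, 4, 4, 4)).astype(np.float32))
    out = cbam.forward(x).data
    serial = cbam.sam.forward(cbam.cam.forward(x)).data
    swapped = cbam.cam.forward(cbam.sam.forward(x)).data
    np.testing.assert_array_equal(out, serial)
    assert not np.allclose(out, swapped)


def test_outputs_finite_over_many_random_inputs(tiny_net):
    rng = np.random.default_rng(123)
    for _ in range(1000):
        x = (rng.standard_normal((1, 8, 8, 8)) * rng.uniform(0.1, 10)).astype(np.float32)
        assert np.isfinite(tiny_net.forward(x).data).all()


def test_state_dict_roundtrip_preserves_forward(tiny_spec, rng):
    a = build_network(tiny_spec, seed=1)
    b = build_network(tiny_spec, seed=2)
    x = rng.standard_normal((1, 16, 16, 8)).astype(np.float32)
    assert not np.allclose(a.forward(x).data, b.forward(x).data)
    b.load_state_dict(a.state_dict())
    np.testing.assert_array_equal(a.forward(x).data, b.forward(x).data)
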