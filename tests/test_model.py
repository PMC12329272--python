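"""Built-network behavior: geometry, ranges, gradients, persistence."""

import numpy as np
import pytest

from unetbench import (
    BlockParams,
    GeometryError,
    VariantSpec,
    build_unet,
    resolve_variant,
    variant_names,
)
from unetbench.nn.layers import BatchNorm2D, Conv2D, fold_batchnorm
from unetbench.nn.losses import bce_with_logits


@pytest.mark.parametrize("size", [64, 256])
def test_shape_preservation_all_variants(size):
    """Output spatial size equals input for every reference variant."""
    x = np.random.default_rng(0).random((1, 1, size, size), dtype=np.float32)
    for name in variant_names():
        model = build_unet(resolve_variant(name), seed=1)
        out = model.predict(x)
        assert out.shape == (1, 1, size, size), name
        assert (out > 0).all() and (out < 1).all(), name  # sigmoid range


def test_single_level_spec_structure():
    model = build_unet(VariantSpec(name="one", encoder_levels=1, initial_filters=2))
    assert len(model.pools) == 1
    assert len(model.decoder) == 1


def test_geometry_error_on_indivisible_input():
    model = build_unet(resolve_variant("U-Net9"))  # needs divisibility by 16
    with pytest.raises(GeometryError):
        model.predict(np.zeros((1, 1, 100, 100), np.float32))
    with pytest.raises(GeometryError):
        model.predict(np.zeros((1, 2, 64, 64), np.float32))


def test_prediction_determinism(small_spec):
    x = np.random.default_rng(3).random((2, 1, 32, 32), dtype=np.float32)
    p1 = build_unet(small_spec, seed=5).predict(x)
    p2 = build_unet(small_spec, seed=5).predict(x)
    np.testing.assert_array_equal(p1, p2)


@pytest.mark.parametrize("use_bn", [False, True])
def test_backprop_matches_finite_differences(use_bn):
    """Analytic gradients of the full net agree with central differences.

    float32 plus ReLU kinks leave a noisy tail, so the assertion is on the
    bulk of sampled coordinates (median and 90th percentile).
    """
    spec = VariantSpec(name="grad", encoder_levels=2, initial_filters=2,
                       use_batchnorm=use_bn)
    model = build_unet(spec, seed=3)
    rng = np.random.default_rng(0)
    x = rng.random((2, 1, 8, 8)).astype(np.float32)
    y = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)

    z = model.forward_logits(x)
    _, dz = bce_with_logits(z, y)
    model.backward(dz)
    params, grads = model.named_parameters(), model.named_grads()

    errs = []
    pick = np.random.default_rng(1)
    for name in params:
        p, g = params[name], grads[name]
        for _ in range(3):
            idx = tuple(pick.integers(0, s) for s in p.shape)
            eps, orig = 1e-3, p[idx]
            p[idx] = orig + eps
            lp, _ = bce_with_logits(model.forward_logits(x), y)
            p[idx] = orig - eps
            lm, _ = bce_with_logits(model.forward_logits(x), y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            errs.append(abs(num - g[idx]) / max(1e-3, abs(num), abs(g[idx])))
    errs = np.array(errs)
    assert np.median(errs) < 1e-3
    assert np.percentile(errs, 90) < 3e-2


def test_block_without_bn_reduces_to_relu_conv(rng):
    w = rng.standard_normal((3, 2, 3, 3)).astype(np.float32)
    b = rng.standard_normal(3).astype(np.float32)
    x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
    block = BlockParams(w_conv=w, b_conv=b)
    conv = Conv2D(2, 3, 3, np.random.default_rng(0))
    conv.params["w"], conv.params["b"] = w, b
    expected = np.maximum(conv.forward(x, train=False), 0.0)
    np.testing.assert_allclose(block.apply(x), expected, rtol=1e-6)


def test_frozen_batchnorm_fold_identity(rng):
    """scale*z + shift equals the explicit (z - mean)/sqrt(var+eps) form."""
    c = 4
    gamma = rng.standard_normal(c).astype(np.float64)
    beta = rng.standard_normal(c).astype(np.float64)
    mean = rng.standard_normal(c)
    var = rng.random(c) + 0.1
    eps = 1e-5
    z = rng.standard_normal((2, c, 5, 5))
    scale, shift = fold_batchnorm(gamma, beta, mean, var, eps)
    direct = gamma[:, None, None] * (z - mean[:, None, None]) / \
        np.sqrt(var[:, None, None] + eps) + beta[:, None, None]
    np.testing.assert_allclose(scale[:, None, None] * z + shift[:, None, None],
                               direct, rtol=1e-10)


def test_batchnorm_eval_uses_running_stats(rng):
    bn = BatchNorm2D(3)
    x = rng.standard_normal((4, 3, 5, 5)).astype(np.float32)
    bn.forward(x, train=True)
    scale, shift = fold_batchnorm(bn.params["gamma"], bn.params["beta"],
                                  bn.buffers["running_mean"],
                                  bn.buffers["running_var"], bn.epsilon)
    expected = scale[:, None, None] * x + shift[:, None, None]
    np.testing.assert_allclose(bn.forward(x, train=False), expected, atol=1e-5)


def test_blockparams_rejects_bad_stats():
    w = np.zeros((1, 1, 3, 3))
    with pytest.raises(ValueError):
        BlockParams(w_conv=w, b_conv=np.zeros(1), epsilon=0.0)
    with pytest.raises(ValueError):
        BlockParams(w_conv=w, b_conv=np.zeros(1), gamma=np.ones(1),
                    beta=np.zeros(1), batch_mean=np.zeros(1),
                    batch_var=-np.ones(1))


def test_weights_roundtrip(tmp_path, small_spec):
    model = build_unet(small_spec, seed=2)
    x = np.random.default_rng(0).random((1, 1, 32, 32), dtype=np.float32)
    before = model.predict(x)
    path = tmp_path / "ckpt.npz"
    model.save_weights(path)
    other = build_unet(small_spec, seed=99)
    assert not np.allclose(other.predict(x), before)
    other.load_weights(path)
    np.testing.assert_array_equal(other.predict(x), before)
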