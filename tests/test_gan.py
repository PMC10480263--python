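"""Conditional-adversarial model: architecture conformance, numerical
correctness of the layer engine, training behaviour, transfer freezing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

from cbctrepair.gan import (
    GeneratorSpec,
    Pix2PixGAN,
    build_discriminator,
    build_generator,
    denormalize_hu,
    normalize_hu,
)
from cbctrepair.nn import Conv2d, ConvTranspose2d
from cbctrepair.nn.layers import BatchNorm2d

from reference_layers import FULL_SCALE_GENERATOR_LAYERS


# -- normalisation ----------------------------------------------------------

@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    hu=st.lists(st.floats(min_value=-1024.0, max_value=3071.0, width=32),
                min_size=1, max_size=64)
)
def test_hu_normalisation_roundtrip_property(hu):
    img = np.asarray(hu, np.float32)
    assert np.all(np.abs(denormalize_hu(normalize_hu(img)) - img) < 1e-3)
    assert np.all(normalize_hu(img) >= -1.0) and np.all(normalize_hu(img) <= 1.0)


def test_hu_normalisation_endpoints_and_roundtrip():
    assert normalize_hu(np.float32(-1024.0)) == -1.0
    assert normalize_hu(np.float32(3071.0)) == 1.0
    rng = np.random.default_rng(0)
    img = rng.uniform(-1024, 3071, (32, 32)).astype(np.float32)
    back = denormalize_hu(normalize_hu(img))
    assert np.abs(back - img).max() < 1e-3


# -- architecture -----------------------------------------------------------

def test_full_scale_generator_layer_sequence():
    gen = build_generator(GeneratorSpec(input_size=512, base_filters=4, encoder_depth=8))
    listing = gen.layer_listing()
    assert len(listing) == 61
    assert listing == FULL_SCALE_GENERATOR_LAYERS


def test_generator_forward_preserves_shape_and_bottleneck_size():
    gen = build_generator(GeneratorSpec(input_size=512, base_filters=2, encoder_depth=8), seed=0)
    x = np.zeros((1, 1, 512, 512), np.float32)
    y = gen.forward(x, training=False)
    assert y.shape == (1, 1, 512, 512)
    # innermost encoder activation: 512 / 2^8 = 2 px
    assert gen._enc_shapes[-1][2:] == (2, 2)


def test_generator_spec_validation():
    with pytest.raises(ValueError, match="bottleneck"):
        GeneratorSpec(input_size=48, encoder_depth=8)
    with pytest.raises(ValueError, match="final_activation"):
        GeneratorSpec(final_activation="relu")


def test_discriminator_is_patch_level_and_deterministic():
    d1 = build_discriminator(base_filters=8, seed=3)
    d2 = build_discriminator(base_filters=8, seed=3)
    x = np.random.default_rng(0).normal(0, 0.3, (1, 2, 128, 128)).astype(np.float32)
    s1, s2 = d1.forward(x, False), d2.forward(x, False)
    assert s1.shape[2] > 1 and s1.shape[3] > 1  # grid of patch decisions
    np.testing.assert_array_equal(s1, s2)
    assert [l.checksum() for l in d1.all_layers()] == [l.checksum() for l in d2.all_layers()]


def test_discriminator_receptive_field_is_70px():
    from cbctrepair.gan import PatchDiscriminator

    assert PatchDiscriminator.receptive_field() == 70
    # empirical check: gradient support of one interior output unit through
    # the convolution stack (normalisation bypassed — its batch statistics
    # couple all positions and would mask the geometric receptive field)
    d = build_discriminator(base_filters=4, seed=1)
    d.bns = [None] * len(d.bns)
    x = np.random.default_rng(1).normal(0, 0.3, (1, 2, 128, 128)).astype(np.float32)
    s = d.forward(x, False)
    g = np.zeros_like(s)
    g[0, 0, s.shape[2] // 2, s.shape[3] // 2] = 1.0
    gi = d.backward(g)
    rows = np.nonzero(np.abs(gi).sum(axis=(0, 1, 3)))[0]
    cols = np.nonzero(np.abs(gi).sum(axis=(0, 1, 2)))[0]
    assert rows.max() - rows.min() + 1 == 70
    assert cols.max() - cols.min() + 1 == 70


# -- layer-engine numerics --------------------------------------------------

def test_strided_convolution_matches_direct_correlation():
    rng = np.random.default_rng(2)
    conv = Conv2d(2, 3, k=4, stride=2, pad=1, rng=rng)
    x = rng.normal(0, 1, (1, 2, 12, 12)).astype(np.float32)
    y = conv.forward(x, False)
    xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1)))
    for f in range(3):
        direct = sum(
            correlate2d(xp[c], conv.params["w"][f, c], mode="valid") for c in range(2)
        )[::2, ::2] + conv.params["b"][f]
        np.testing.assert_allclose(y[0, f], direct, rtol=1e-4, atol=1e-4)


def test_transposed_convolution_is_exact_adjoint_of_convolution():
    """<conv(x), z> == <x, conv^T(z)> when the two share one weight tensor."""
    rng = np.random.default_rng(3)
    conv = Conv2d(3, 5, k=4, stride=2, pad=1, rng=rng)
    tconv = ConvTranspose2d(5, 3, k=4, stride=2, pad=1, rng=rng)
    tconv.params["w"] = conv.params["w"].copy()  # shapes coincide: (5,3,4,4)^T roles
    tconv.params["b"][...] = 0.0
    conv.params["b"][...] = 0.0
    x = rng.normal(0, 1, (1, 3, 16, 16)).astype(np.float64).astype(np.float32)
    z = rng.normal(0, 1, (1, 5, 8, 8)).astype(np.float64).astype(np.float32)
    lhs = float((conv.forward(x, False) * z).sum())
    rhs = float((x * tconv.forward(z, False)).sum())
    assert abs(lhs - rhs) < 1e-2 * max(1.0, abs(lhs))


def test_batchnorm_gradient_matches_finite_differences():
    rng = np.random.default_rng(4)
    bn = BatchNorm2d(2, rng=rng)
    for k in bn.params:
        bn.params[k] = bn.params[k].astype(np.float64)
        bn.grads[k] = np.zeros_like(bn.params[k])
    x = rng.normal(0, 1, (2, 2, 5, 5))

    def loss():
        return 0.5 * float((bn.forward(x, True) ** 2).sum())

    y = bn.forward(x, True)
    bn.zero_grad()
    bn.backward(y)
    eps = 1e-6
    for k in ("gamma", "beta"):
        orig = bn.params[k][0]
        bn.params[k][0] = orig + eps
        lp = loss()
        bn.params[k][0] = orig - eps
        lm = loss()
        bn.params[k][0] = orig
        assert abs(bn.grads[k][0] - (lp - lm) / (2 * eps)) < 1e-5


# -- training ---------------------------------------------------------------

def test_training_reduces_l1_and_is_deterministic(trained_model, training_pairs):
    assert trained_model.history_[-1]["g_l1"] < trained_model.history_[0]["g_l1"]
    X, Y = training_pairs
    a = Pix2PixGAN(input_size=64, base_filters=8, encoder_depth=6, epochs=2, seed=4).fit(X, Y)
    b = Pix2PixGAN(input_size=64, base_filters=8, encoder_depth=6, epochs=2, seed=4).fit(X, Y)
    assert a.generator_.checksums() == b.generator_.checksums()


def test_zero_epochs_rejected(training_pairs):
    X, Y = training_pairs
    with pytest.raises(ValueError, match="epochs"):
        Pix2PixGAN(input_size=64, base_filters=8, encoder_depth=6, epochs=0).fit(X, Y)


def test_identity_task_overfits_to_near_zero_l1():
    """A generator trained on input == target drives the L1 term near zero."""
    rng = np.random.default_rng(7)
    img = rng.uniform(-1000, 1500, (1, 32, 32)).astype(np.float32)
    est = Pix2PixGAN(
        input_size=32, base_filters=8, encoder_depth=5, epochs=400, seed=2,
        n_dropout_stages=0,
    )
    est.fit(img, img)
    assert est.history_[-1]["g_l1"] < 0.05
    assert est.history_[-1]["g_l1"] < 0.1 * est.history_[0]["g_l1"]


def test_inference_contract(trained_model):
    rng = np.random.default_rng(8)
    X = rng.uniform(-1024, 3071, (3, 64, 64)).astype(np.float32)
    out = trained_model.predict(X)
    assert out.shape == X.shape
    assert out.min() >= -1024.0 and out.max() <= 3071.0
    # batch output matches per-slice calls, in order
    for i in range(3):
        np.testing.assert_array_equal(out[i], trained_model.predict(X[i]))


# -- transfer learning ------------------------------------------------------

def test_transfer_changes_exactly_the_last_two_layers(trained_model, training_pairs):
    X, Y = training_pairs
    before = trained_model.generator_.checksums()
    adapted = trained_model.transfer(X[:4], Y[:4], epochs=1, seed=7)
    after = adapted.generator_.checksums()
    changed = [i for i, (b, a) in enumerate(zip(before, after)) if b != a]
    assert changed == [len(before) - 2, len(before) - 1]
    # layer-by-layer equality of every frozen layer; base model untouched
    assert before[: -2] == after[: -2]
    assert trained_model.generator_.checksums() == before


def test_transfer_zero_epochs_is_identity(trained_model, training_pairs):
    X, Y = training_pairs
    same = trained_model.transfer(X[:2], Y[:2], epochs=0, seed=7)
    assert same.generator_.checksums() == trained_model.generator_.checksums()


def test_transfer_freeze_mask_validation(trained_model, training_pairs):
    X, Y = training_pairs
    n_layers = len(trained_model.generator_.parameterized_layers())
    with pytest.raises(ValueError, match="n_trainable"):
        trained_model.transfer(X[:2], Y[:2], epochs=1, n_trainable_param_layers=n_layers + 1)
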