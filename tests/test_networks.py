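"""Shape, normalisation and determinism contracts of the networks."""

import warnings

import numpy as np
import pytest

from mindsct.autodiff import Tensor
from mindsct.networks import (Discriminator, Generator, MultiScaleDiscriminator,
                              adalin, cam_attend, discriminate, instance_norm,
                              layer_norm, translate)


def _features(rng, shape=(1, 2, 4, 4)):
    return rng.normal(size=shape)


# ------------------------------------------------------------------ adalin
def test_adalin_rho_one_is_instance_norm(rng):
    x = _features(rng)
    got = adalin(x, np.ones(2), np.zeros(2), rho=1.0)
    want = instance_norm(Tensor(x)).data
    assert np.abs(got - want).max() < 1e-6


def test_adalin_rho_zero_is_layer_norm(rng):
    x = _features(rng)
    got = adalin(x, np.ones(2), np.zeros(2), rho=0.0)
    want = layer_norm(Tensor(x)).data
    assert np.abs(got - want).max() < 1e-6


def test_adalin_half_blend_matches_statistics_oracle(rng):
    x = _features(rng)
    eps = 1e-5
    # direct statistics oracle, written independently of the layer code
    mu_in = x.mean(axis=(2, 3), keepdims=True)
    var_in = x.var(axis=(2, 3), keepdims=True)
    mu_ln = x.mean(axis=(1, 2, 3), keepdims=True)
    var_ln = x.var(axis=(1, 2, 3), keepdims=True)
    blend = 0.5 * (x - mu_in) / np.sqrt(var_in + eps) \
        + 0.5 * (x - mu_ln) / np.sqrt(var_ln + eps)
    gamma = np.array([2.0, 0.5])
    beta = np.array([0.1, -0.3])
    want = gamma[None, :, None, None] * blend + beta[None, :, None, None]
    got = adalin(x, gamma, beta, rho=0.5)
    assert np.abs(got - want).max() < 1e-6


def test_adalin_clamps_out_of_range_rho(rng):
    x = _features(rng)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        got = adalin(x, np.ones(2), np.zeros(2), rho=1.7)
    assert any("clamped" in str(w.message) for w in caught)
    want = adalin(x, np.ones(2), np.zeros(2), rho=1.0)
    assert np.allclose(got, want)


# ------------------------------------------------------------------- CAM
def test_cam_uniform_weights_keep_features_proportional(rng):
    x = np.abs(_features(rng))  # positive so relu is inactive
    attended, logit = cam_attend(x, np.ones(2))
    assert np.allclose(attended, x)
    assert logit[0, 0] == pytest.approx(x.mean(axis=(2, 3)).sum())


def test_cam_one_hot_weight_selects_channel(rng):
    x = np.abs(_features(rng))
    attended, _ = cam_attend(x, np.array([0.0, 1.0]))
    assert np.allclose(attended[:, 0], 0.0)
    assert np.allclose(attended[:, 1], x[:, 1])


def test_cam_matches_weighted_sum_oracle(rng):
    x = _features(rng, (2, 3, 4, 4))
    w = rng.normal(size=3)
    attended, logit = cam_attend(x, w)
    want_logit = x.mean(axis=(2, 3)) @ w
    assert np.allclose(logit[:, 0], want_logit)
    assert np.allclose(attended, np.maximum(x * w[None, :, None, None], 0.0))
    assert attended.min() >= 0.0


def test_cam_channel_mismatch_raises(rng):
    with pytest.raises(ValueError):
        cam_attend(_features(rng), np.ones(5))


# -------------------------------------------------------------- generator
@pytest.mark.parametrize("size", [16, 32, 64])
def test_translate_preserves_shape(size, rng):
    gen = Generator(base_width=4, n_down=2, n_res=1, seed=0)
    img = rng.uniform(size=(size, size)).astype(np.float32)
    out, attention, logit = translate(gen, img)
    assert out.shape == (size, size)
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert np.isfinite(logit)


def test_translate_pads_and_crops_indivisible_sizes(rng):
    gen = Generator(base_width=4, n_down=2, n_res=1, seed=0)
    img = rng.uniform(size=(18, 22)).astype(np.float32)
    with pytest.warns(UserWarning, match="padding"):
        out, _, _ = translate(gen, img)
    assert out.shape == (18, 22)


def test_translate_batch_shape(rng):
    gen = Generator(base_width=4, n_down=2, n_res=1, seed=0)
    imgs = rng.uniform(size=(3, 16, 16)).astype(np.float32)
    out, attention, logits = translate(gen, imgs)
    assert out.shape == (3, 16, 16)
    assert logits.shape == (3,)


def test_translate_deterministic(rng):
    img = rng.uniform(size=(16, 16)).astype(np.float32)
    a = translate(Generator(base_width=4, n_res=1, seed=3), img)[0]
    b = translate(Generator(base_width=4, n_res=1, seed=3), img)[0]
    assert np.array_equal(a, b)


def test_zero_head_weights_give_constant_output(rng):
    gen = Generator(base_width=4, n_res=1, seed=0)
    gen.head.weight.data[:] = 0.0
    gen.head.bias.data[:] = 0.0
    out, _, _ = translate(gen, rng.uniform(size=(16, 16)).astype(np.float32))
    assert np.allclose(out, 0.5)  # tanh(0) mapped to [0, 1]


def test_rho_values_respect_bounds():
    gen = Generator(base_width=4, n_res=2, seed=0)
    vals = gen.rho_values()
    assert np.all(vals >= 0.0) and np.all(vals <= 1.0)
    gen.dec_res[0].rho1.data += 5.0
    gen.clamp_rho()
    assert gen.rho_values().max() <= 1.0


# ---------------------------------------------------------- discriminator
def test_zero_weight_discriminator_is_indifferent(rng):
    d = Discriminator(base_width=4, n_layers=2, spectral_norm=False, seed=0)
    for conv in d.convs + [d.cam_fuse, d.head]:
        conv.weight.data[:] = 0.0
        if conv.bias is not None:
            conv.bias.data[:] = 0.0
    d.cam_fc.weight.data[:] = 0.0
    realness, logit = discriminate(d, rng.uniform(size=(16, 16)), apply_sigmoid=True)
    assert np.allclose(realness, 0.5)
    assert logit == pytest.approx(0.0)


@pytest.mark.parametrize("size,n_layers", [(16, 2), (64, 3)])
def test_realness_map_follows_stage_arithmetic(size, n_layers, rng):
    d = Discriminator(base_width=4, n_layers=n_layers, seed=0)
    realness, _ = discriminate(d, rng.uniform(size=(size, size)))
    side = size
    for _ in range(n_layers):
        side = side // 2
    assert realness.shape == (side - 1, side - 1)  # 4×4 valid head conv, pad 1


def test_multiscale_discriminator_emits_per_scale_outputs(rng):
    d = MultiScaleDiscriminator(base_width=4, n_layers=2, scales=2, seed=0)
    maps, logits = discriminate(d, rng.uniform(size=(16, 16)))
    assert len(maps) == 2 and len(logits) == 2
    assert maps[1].shape[0] < maps[0].shape[0]


def test_discriminator_deterministic(rng):
    img = rng.uniform(size=(16, 16))
    a = discriminate(Discriminator(base_width=4, n_layers=2, seed=5), img)[0]
    b = discriminate(Discriminator(base_width=4, n_layers=2, seed=5), img)[0]
    assert np.array_equal(a, b)


# ----------------------------------------------------------- gradient flow
def test_every_objective_component_reaches_its_parameters(rng):
    """Each loss term must push nonzero gradients into its parameter set."""
    from mindsct.losses import adv_loss_ls, cam_loss_generator
    from mindsct.mind import MINDConfig, mind_loss_tensor

    gen = Generator(base_width=4, n_down=2, n_res=1, seed=1)
    disc = Discriminator(base_width=4, n_layers=2, spectral_norm=False, seed=2)
    x = Tensor(rng.uniform(size=(1, 1, 16, 16)).astype(np.float32))
    y = Tensor(rng.uniform(size=(1, 1, 16, 16)).astype(np.float32))

    def grad_norm(params):
        return sum(0.0 if p.grad is None else float(np.abs(p.grad).sum())
                   for p in params)

    fake, _, logit = gen(x)
    cycle = (fake - x).abs().mean()
    gen.zero_grad()
    cycle.backward()
    assert grad_norm(gen.parameters()) > 0

    gen.zero_grad()
    disc.zero_grad()
    fake, _, logit = gen(x)
    realness, _ = disc(fake)
    g_term, _ = adv_loss_ls(realness.detach(), realness)
    g_term.backward()
    assert grad_norm(gen.parameters()) > 0

    gen.zero_grad()
    _, _, logit_src = gen(x)
    _, _, logit_tgt = gen(y)
    cam = cam_loss_generator(logit_src.sigmoid(), logit_tgt.sigmoid())
    cam.backward()
    assert grad_norm([gen.cam_fc.weight]) > 0

    gen.zero_grad()
    fake, _, _ = gen(x)
    mind = mind_loss_tensor(fake, x, MINDConfig.from_radii(1, 1))
    mind.backward()
    assert grad_norm(gen.parameters()) > 0

    disc.zero_grad()
    realness, _ = disc(y)
    _, d_term = adv_loss_ls(realness, realness.detach())
    d_term.backward()
    assert grad_norm(disc.parameters()) > 0
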