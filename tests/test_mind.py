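"""The neighbourhood descriptor against an independent nested-loop oracle."""

import numpy as np
import pytest

from mindsct.autodiff import Tensor
from mindsct.mind import (MINDConfig, MINDDescriptor, build_shift_set,
                          compute_mind, four_neighbourhood, local_variance,
                          mind_descriptor_tensor, mind_loss, mind_loss_tensor,
                          patch_distance)
from mindsct.phantom import PhantomConfig, generate_phantom


# ----------------------------------------------------------------- oracles
def oracle_patch_distance(img, r, patch_offsets):
    """Direct double-loop evaluation of the patch SSD with clamped reads."""
    H, W = img.shape

    def I(y, x):
        return img[min(max(y, 0), H - 1), min(max(x, 0), W - 1)]

    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for (py, px) in patch_offsets:
                acc += (I(y + py, x + px) - I(y + r[0] + py, x + r[1] + px)) ** 2
            out[y, x] = acc
    return out


def oracle_mind(img, config):
    """Per-pixel oracle of the descriptor: distances, variance, exponential,
    channel-max normalisation — all via the nested-loop distance."""
    V = np.zeros(img.shape)
    for n in config.variance_offsets:
        V += oracle_patch_distance(img, n, config.patch_offsets)
    floor = config.variance_floor_fraction * V.mean()
    V = np.maximum(np.maximum(V, floor), 1e-30)
    chans = [np.exp(-oracle_patch_distance(img, r, config.patch_offsets) / V)
             for r in config.search_offsets]
    desc = np.stack(chans, axis=-1)
    return desc / desc.max(axis=-1, keepdims=True)


# ----------------------------------------------------------------- shifts
def test_shift_set_sizes_and_order():
    s4 = build_shift_set(4)
    assert len(s4) == 81
    assert s4[0] == (-4, -4) and s4[-1] == (4, 4)
    assert len(set(s4)) == 81
    assert build_shift_set(0) == [(0, 0)]
    assert len(build_shift_set(1)) == 9
    # canonical row-major order
    assert s4 == sorted(s4)


def test_shift_set_rejects_negative_radius():
    with pytest.raises(ValueError):
        build_shift_set(-1)


# ---------------------------------------------------------- patch distance
def test_patch_distance_trivial_cases(rng):
    const = np.full((8, 8), 0.7)
    assert np.allclose(patch_distance(const, (2, 1)), 0.0)
    img = rng.uniform(size=(8, 8))
    assert np.allclose(patch_distance(img, (0, 0)), 0.0)


def test_patch_distance_matches_nested_loop_oracle(rng):
    img = rng.uniform(size=(8, 8))
    P = build_shift_set(1)
    for r in [(1, 0), (0, 1), (-1, 1), (2, -2)]:
        got = patch_distance(img, r, P)
        want = oracle_patch_distance(img, r, P)
        assert np.allclose(got, want, atol=1e-12)


def test_patch_distance_rejects_small_images(rng):
    with pytest.raises(ValueError):
        patch_distance(rng.uniform(size=(3, 3)), (4, 0))


# ---------------------------------------------------------- local variance
def test_local_variance_constant_image_hits_floor():
    const = np.full((8, 8), 0.3)
    V = local_variance(const)
    assert np.all(V > 0)
    assert np.allclose(V, V.flat[0])  # uniform floor value


def test_local_variance_quadratic_scaling(rng):
    img = rng.uniform(size=(8, 8))
    V1 = local_variance(img)
    V2 = local_variance(4.0 * img)
    assert np.allclose(V2, 16.0 * V1, rtol=1e-10)


def test_local_variance_composes_patch_distance_oracle(rng):
    img = rng.uniform(size=(8, 8))
    P = build_shift_set(1)
    raw = sum(oracle_patch_distance(img, n, P) for n in four_neighbourhood())
    floor = 1e-3 * raw.mean()
    want = np.maximum(raw, floor)
    assert np.allclose(local_variance(img), want, atol=1e-12)


# ------------------------------------------------------------- descriptor
def test_constant_image_descriptor_is_all_ones(small_mind_config):
    desc = compute_mind(np.full((10, 10), 0.5), small_mind_config)
    assert np.allclose(desc, 1.0)


def test_channel_max_is_one_everywhere(rng, small_mind_config):
    for _ in range(5):
        img = rng.uniform(size=(12, 12))
        desc = compute_mind(img, small_mind_config)
        assert np.allclose(desc.max(axis=-1), 1.0, atol=1e-6)
        assert desc.min() > 0.0


def test_affine_intensity_invariance(small_mind_config):
    for seed in range(20):
        img = np.random.default_rng(seed).uniform(size=(10, 10))
        base = compute_mind(img, small_mind_config)
        for a, b in [(0.5, 0.0), (2.0, 1.0), (10.0, -3.0), (0.5, 7.0), (2.0, -0.2)]:
            other = compute_mind(a * img + b, small_mind_config)
            assert np.abs(other - base).max() < 1e-6


def test_descriptor_matches_oracle_radius1(rng, small_mind_config):
    img = rng.uniform(size=(10, 10))
    got = compute_mind(img, small_mind_config)
    want = oracle_mind(img, small_mind_config)
    assert np.abs(got - want).max() < 1e-8


def test_tensor_path_matches_numpy_path(rng, small_mind_config):
    img = rng.uniform(size=(12, 12))
    dt = mind_descriptor_tensor(Tensor(img[None, None]), small_mind_config)
    dn = compute_mind(img, small_mind_config)
    assert np.abs(dt.data[0].transpose(1, 2, 0) - dn).max() < 1e-12


# ------------------------------------------------------------------- loss
def test_mind_loss_pseudo_metric_properties(rng, small_mind_config):
    x = rng.uniform(size=(10, 10))
    y = rng.uniform(size=(10, 10))
    assert mind_loss(x, x, small_mind_config) == 0.0
    assert mind_loss(x, 3.0 * x + 0.5, small_mind_config) < 1e-7
    d_xy = mind_loss(x, y, small_mind_config)
    d_yx = mind_loss(y, x, small_mind_config)
    assert d_xy == pytest.approx(d_yx, abs=1e-15)
    assert d_xy > 0


def test_mind_loss_matches_oracle(rng, small_mind_config):
    x = rng.uniform(size=(10, 10))
    y = rng.uniform(size=(10, 10))
    want = np.mean(np.abs(oracle_mind(x, small_mind_config)
                          - oracle_mind(y, small_mind_config)))
    assert mind_loss(x, y, small_mind_config) == pytest.approx(want, abs=1e-10)


def test_mind_loss_shape_mismatch(rng, small_mind_config):
    with pytest.raises(ValueError):
        mind_loss(rng.uniform(size=(10, 10)), rng.uniform(size=(12, 12)),
                  small_mind_config)


def test_translation_increases_mind_loss(small_mind_config):
    """Shifting a structured phantom must strictly increase the loss."""
    config = PhantomConfig(size=32, noise_std=0.0)
    for seed in range(10):
        img = generate_phantom(config, "ct_style", seed).image
        shifted = np.roll(img, 3, axis=1)
        assert mind_loss(img, shifted, small_mind_config) > 0.0


def test_mind_loss_tensor_matches_scalar(rng, small_mind_config):
    x = rng.uniform(size=(10, 10))
    y = rng.uniform(size=(10, 10))
    lt = mind_loss_tensor(Tensor(x[None, None]), Tensor(y[None, None]),
                          small_mind_config)
    assert float(lt.data) == pytest.approx(mind_loss(x, y, small_mind_config),
                                           abs=1e-12)


# ------------------------------------------------------------- transformer
def test_descriptor_transformer_roundtrip(rng):
    est = MINDDescriptor(search_radius=1, patch_radius=1)
    X = rng.uniform(size=(3, 10, 10))
    out = est.fit_transform(X)
    assert out.shape == (3, 10, 10, 9)
    assert est.n_channels_ == 9
    params = est.get_params()
    assert params["search_radius"] == 1
    single = est.transform(X[0])
    assert np.allclose(single, out[0])
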