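"""Closed-form and elementwise-oracle checks of the objective components."""

import numpy as np
import pytest

from mindsct.losses import (LossWeights, adv_loss_log, adv_loss_ls,
                            cam_loss_discriminator, cam_loss_generator,
                            cycle_loss, identity_loss, total_loss)


# ----------------------------------------------------------- adversarial
def test_log_loss_perfect_discrimination_vanishes():
    _, d = adv_loss_log(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
    assert d == pytest.approx(0.0, abs=1e-5)


def test_log_loss_coin_flip_closed_form():
    g, d = adv_loss_log(np.array([0.5]), np.array([0.5]))
    assert d == pytest.approx(2 * np.log(2), abs=1e-12)
    assert g == pytest.approx(np.log(2), abs=1e-12)


def test_log_loss_matches_elementwise_oracle(rng):
    dr = rng.uniform(0.05, 0.95, size=4)
    df = rng.uniform(0.05, 0.95, size=4)
    g, d = adv_loss_log(dr, df)
    assert d == pytest.approx(-np.mean(np.log(dr)) - np.mean(np.log(1 - df)))
    assert g == pytest.approx(-np.mean(np.log(df)))


def test_log_loss_finite_at_extreme_scores():
    g, d = adv_loss_log(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    assert np.isfinite(g) and np.isfinite(d)


def test_ls_loss_closed_forms(rng):
    _, d = adv_loss_ls(np.array([1.0]), np.array([0.0]))
    assert d == 0.0
    g, d = adv_loss_ls(np.array([0.5]), np.array([0.5]))
    assert d == pytest.approx(0.5)
    assert g == pytest.approx(0.25)
    dr = rng.normal(size=5)
    df = rng.normal(size=5)
    g, d = adv_loss_ls(dr, df)
    assert d == pytest.approx(np.mean((dr - 1) ** 2) + np.mean(df ** 2))
    assert g == pytest.approx(np.mean((df - 1) ** 2))


def test_empty_batch_rejected():
    with pytest.raises(ValueError):
        adv_loss_log(np.array([]), np.array([0.5]))
    with pytest.raises(ValueError):
        adv_loss_ls(np.array([0.5]), np.array([]))


# ------------------------------------------------------- cycle / identity
def test_cycle_loss_zero_for_exact_inverses(rng):
    a = rng.uniform(size=(2, 6, 6))
    b = rng.uniform(size=(2, 6, 6))
    ident = lambda x: x  # noqa: E731
    assert cycle_loss(ident, ident, a, b) == 0.0
    plus = lambda x: x + 0.3  # noqa: E731
    minus = lambda x: x - 0.3  # noqa: E731
    assert cycle_loss(plus, minus, a, b) == pytest.approx(0.0, abs=1e-12)


def test_cycle_loss_closed_form_on_ones():
    ones = np.ones((1, 4, 4))
    double = lambda x: 2.0 * x  # noqa: E731
    ident = lambda x: x  # noqa: E731
    # a->b->a: |2a - a| = 1 ; b->a->b: |2b - b| = 1
    assert cycle_loss(double, ident, ones, ones) == pytest.approx(2.0)


def test_identity_loss_cases(rng):
    a = rng.uniform(size=(2, 5, 5))
    b = rng.uniform(size=(2, 5, 5))
    ident = lambda x: x  # noqa: E731
    assert identity_loss(ident, ident, a, b) == 0.0
    double = lambda x: 2.0 * x  # noqa: E731
    ones = np.ones((1, 4, 4))
    assert identity_loss(double, ident, ones, ones) == pytest.approx(1.0)
    # affine generators vs elementwise oracle
    g_ab = lambda x: 1.5 * x + 0.1  # noqa: E731
    g_ba = lambda x: 0.5 * x  # noqa: E731
    want = np.mean(np.abs(g_ab(b) - b)) + np.mean(np.abs(g_ba(a) - a))
    assert identity_loss(g_ab, g_ba, a, b) == pytest.approx(want)


def test_cycle_loss_rejects_shape_change():
    shrink = lambda x: x[:, :2, :2]  # noqa: E731
    ident = lambda x: x  # noqa: E731
    with pytest.raises(ValueError):
        cycle_loss(shrink, ident, np.ones((1, 4, 4)), np.ones((1, 4, 4)))


# ------------------------------------------------------------------- CAM
def test_cam_generator_separated_domains_vanish():
    assert cam_loss_generator(np.array([1.0]), np.array([0.0])) == \
        pytest.approx(0.0, abs=1e-5)


def test_cam_generator_coin_flip():
    assert cam_loss_generator(np.array([0.5]), np.array([0.5])) == \
        pytest.approx(2 * np.log(2))


def test_cam_generator_oracle(rng):
    es = rng.uniform(0.1, 0.9, size=3)
    et = rng.uniform(0.1, 0.9, size=3)
    want = -(np.mean(np.log(es)) + np.mean(np.log(1 - et)))
    assert cam_loss_generator(es, et) == pytest.approx(want)


def test_cam_discriminator_forms(rng):
    assert cam_loss_discriminator(np.array([1.0]), np.array([0.0])) == 0.0
    assert cam_loss_discriminator(np.array([0.5]), np.array([0.5])) == \
        pytest.approx(0.5)
    er = rng.normal(size=4)
    ef = rng.normal(size=4)
    want = np.mean((er - 1) ** 2) + np.mean(ef ** 2)
    assert cam_loss_discriminator(er, ef) == pytest.approx(want)


# ------------------------------------------------------------------ totals
def _unit_components(variant, with_mind):
    keys = ["adv_g_ab", "adv_g_ba", "adv_d_ab", "adv_d_ba", "cycle", "identity"]
    if variant == "ugatit":
        keys += ["cam_g_ab", "cam_g_ba", "cam_d_ab", "cam_d_ba"]
    if with_mind:
        keys.append("mind")
    return {k: 1.0 for k in keys}


def test_total_zero_components_zero_total():
    comps = {k: 0.0 for k in _unit_components("ugatit", True)}
    rep = total_loss("ugatit", True, comps)
    assert rep.total_g == 0.0 and rep.total_d == 0.0


def test_total_unit_components_published_cyclegan_mind_weights():
    rep = total_loss("cyclegan", True, _unit_components("cyclegan", True))
    # 1 + 1 + 10*1 + 0.5*1 + 20*1
    assert rep.total_g == pytest.approx(32.5)
    assert rep.total_d == pytest.approx(2.0)


def test_total_unit_components_published_ugatit_mind_weights():
    rep = total_loss("ugatit", True, _unit_components("ugatit", True))
    # 2 + 100 + 100 + 100*2 + 5000
    assert rep.total_g == pytest.approx(5402.0)
    assert rep.total_d == pytest.approx(2.0 + 100.0 * 2.0)


def test_doubling_lambda_mind_shifts_total_by_mind_component():
    comps = _unit_components("cyclegan", True)
    comps["mind"] = 0.37
    w1 = LossWeights(10.0, 0.5, 0.0, 20.0)
    w2 = LossWeights(10.0, 0.5, 0.0, 40.0)
    r1 = total_loss("cyclegan", True, comps, w1)
    r2 = total_loss("cyclegan", True, comps, w2)
    assert r2.total_g - r1.total_g == pytest.approx(20.0 * 0.37)
    assert r2.total_d == r1.total_d


@pytest.mark.parametrize("component,weight_attr", [
    ("cycle", "lambda_cycle"),
    ("identity", "lambda_identity"),
    ("mind", "lambda_mind"),
])
def test_total_is_linear_in_each_component(component, weight_attr):
    """Slope of total_g in a component equals its λ, across three λ values."""
    for lam in (0.5, 2.0, 7.0):
        kw = {"lambda_cycle": 1.0, "lambda_identity": 1.0, "lambda_cam": 1.0,
              "lambda_mind": 1.0}
        kw[weight_attr] = lam
        w = LossWeights(**kw)
        lo = _unit_components("ugatit", True)
        hi = dict(lo)
        hi[component] = lo[component] + 1.0
        slope = (total_loss("ugatit", True, hi, w).total_g
                 - total_loss("ugatit", True, lo, w).total_g)
        assert slope == pytest.approx(lam)


def test_total_missing_component_raises():
    comps = _unit_components("ugatit", True)
    comps.pop("cam_d_ba")
    with pytest.raises(KeyError):
        total_loss("ugatit", True, comps)
    with pytest.raises(KeyError):
        total_loss("cyclegan", False, _unit_components("ugatit", False))


def test_weights_reject_negative():
    with pytest.raises(ValueError):
        LossWeights(lambda_cycle=-1.0)


def test_published_default_weights():
    cg = LossWeights.cyclegan_defaults(with_mind=True)
    assert (cg.lambda_cycle, cg.lambda_identity, cg.lambda_mind) == (10.0, 0.5, 20.0)
    ug = LossWeights.ugatit_defaults(with_mind=True)
    assert (ug.lambda_cycle, ug.lambda_identity, ug.lambda_cam,
            ug.lambda_mind) == (100.0, 100.0, 100.0, 5000.0)
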