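"""Rubric scoring, overlap proxies and the paired method comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mindsct.evaluation import (MisalignmentCounts, compare_methods, dice,
                                extract_bone_mask, rubric_score,
                                structure_report, summarize_scores)
from mindsct.phantom import PhantomConfig, generate_phantom, PhantomSample


# ------------------------------------------------------------------ rubric
def oracle_rubric(major, minor):
    """Brute-force rule evaluation in severity order, written independently."""
    rules = [
        (1, lambda M, m: M >= 10),
        (2, lambda M, m: M >= 5),
        (3, lambda M, m: M >= 3 or m >= 15),
        (4, lambda M, m: M >= 1 or m >= 10),
    ]
    for score, rule in rules:
        if rule(major, minor):
            return score
    return 5


@pytest.mark.parametrize("major,minor,want", [
    (10, 0, 1),   # ten or more major
    (5, 0, 2),    # five or more major
    (3, 0, 3),    # three or more major
    (0, 15, 3),   # fifteen or more minor
    (1, 0, 4),    # one or more major
    (0, 10, 4),   # ten or more minor
    (0, 9, 5),    # matches no rule
    (0, 0, 5),    # clean case set
    (2, 9, 4),    # fails rules 1-3, matches "1 or more major"
    (12, 20, 1),  # severity order: rule for 1 point wins
])
def test_rubric_worked_examples(major, minor, want):
    assert rubric_score(MisalignmentCounts(major, minor)) == want


def test_rubric_exhaustive_sweep_matches_oracle():
    for major in range(21):
        for minor in range(21):
            assert rubric_score(MisalignmentCounts(major, minor)) == \
                oracle_rubric(major, minor), (major, minor)


def test_rubric_monotone_in_both_counts():
    for major in range(20):
        for minor in range(20):
            here = rubric_score(MisalignmentCounts(major, minor))
            assert rubric_score(MisalignmentCounts(major + 1, minor)) <= here
            assert rubric_score(MisalignmentCounts(major, minor + 1)) <= here


def test_rubric_rejects_negative_counts():
    with pytest.raises(ValueError):
        MisalignmentCounts(-1, 0)


# -------------------------------------------------------------------- dice
def test_dice_closed_forms():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    assert dice(a, b) == 1.0  # both empty
    a[0, :4] = True
    assert dice(a, a) == 1.0
    b[1, :4] = True
    assert dice(a, b) == 0.0  # disjoint
    c = np.zeros((4, 4), dtype=bool)
    c[0, 2:4] = True
    c[1, 0:2] = True  # |A|=|B|=4, |A∩B|=2
    assert dice(a, c) == pytest.approx(0.5)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 16 - 1))
def test_dice_symmetry_and_bounds(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(8, 8)) > 0.5
    b = rng.uniform(size=(8, 8)) > 0.5
    d = dice(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice(b, a)


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice(np.ones((3, 3), bool), np.ones((4, 4), bool))


# ------------------------------------------------------------- bone masks
def test_bone_mask_recovers_phantom_bones():
    s = generate_phantom(PhantomConfig(size=64), "ct_style", 17)
    mask = extract_bone_mask(s.image)
    assert dice(mask, s.bones) >= 0.9


def test_bone_mask_empty_for_soft_tissue_only():
    img = np.full((16, 16), 0.35)
    assert not extract_bone_mask(img).any()


def test_bone_mask_threshold_zero_is_foreground():
    s = generate_phantom(PhantomConfig(size=32, noise_std=0.0), "ct_style", 2)
    mask = extract_bone_mask(s.image, bone_threshold=0.0, min_size=1)
    # with no noise, only body pixels are strictly above zero
    assert dice(mask, s.body) >= 0.99


# -------------------------------------------------------- structure report
def _ct_rendering(sample: PhantomSample) -> np.ndarray:
    img = np.zeros_like(sample.image)
    img[sample.body] = 0.35
    img[sample.lungs] = 0.08
    img[sample.bones] = 0.9
    return img


def test_structure_report_self_consistent_geometry():
    src = generate_phantom(PhantomConfig(size=64), "mri_style", 23)
    synth = _ct_rendering(src)
    rep = structure_report(src, synth)
    assert rep["bone_dice"] >= 0.9
    assert rep["body_dice"] >= 0.95
    assert rep["centroid_shift"] < 1.0
    assert not rep["collapsed"]


def test_structure_report_detects_translation():
    src = generate_phantom(PhantomConfig(size=64, noise_std=0.0),
                           "mri_style", 31)
    synth = np.roll(_ct_rendering(src), shift=(3, 4), axis=(0, 1))
    rep = structure_report(src, synth)
    assert rep["centroid_shift"] == pytest.approx(5.0, abs=0.6)
    assert rep["bone_dice"] < 0.9


def test_structure_report_flags_constant_collapse():
    src = generate_phantom(PhantomConfig(size=32), "mri_style", 5)
    rep = structure_report(src, np.full_like(src.image, 0.4))
    assert rep["contrast"] == pytest.approx(0.0, abs=1e-12)
    assert rep["collapsed"]


def test_structure_report_shape_mismatch():
    src = generate_phantom(PhantomConfig(size=32), "mri_style", 5)
    with pytest.raises(ValueError):
        structure_report(src, np.zeros((16, 16)))


# --------------------------------------------------------- method compare
def test_identical_scores_never_significant():
    scores = {"m1": np.full(21, 4.0), "m2": np.full(21, 4.0),
              "ref": np.full(21, 4.0)}
    res = compare_methods(scores, "ref")
    assert not any(r["significant"] for r in res.values())
    assert all(r["p_value"] == 1.0 for r in res.values())


def test_uniform_shift_significant_at_corrected_threshold():
    """Reference +2 over 21 cases; the exact tied-rank null gives
    p = 2 * 0.5^21 (all |d| equal, so the statistic is binomial)."""
    rng = np.random.default_rng(0)
    base = rng.integers(1, 4, size=21).astype(float)
    scores = {"ref": base + 2.0, "m1": base, "m2": base + rng.uniform(-0.01, 0.01, 21)}
    res = compare_methods(scores, "ref", alpha=0.001)
    oracle_p = 2.0 * 0.5 ** 21
    assert res["m1"]["threshold"] == pytest.approx(0.001 / 2)
    assert res["m1"]["p_value"] < 0.001 / 2
    assert res["m1"]["significant"]
    # the computed p is within an order of magnitude of the enumeration oracle
    assert res["m1"]["p_value"] < 1e-4
    assert oracle_p < 1e-5


def test_two_methods_bonferroni_threshold_is_alpha():
    scores = {"ref": np.arange(10, dtype=float), "m1": np.zeros(10)}
    res = compare_methods(scores, "ref", alpha=0.001)
    assert res["m1"]["threshold"] == pytest.approx(0.001)


def test_compare_methods_validates_inputs():
    with pytest.raises(ValueError):
        compare_methods({"a": np.ones(5)}, "a")
    with pytest.raises(ValueError):
        compare_methods({"a": np.ones(5), "b": np.ones(6)}, "a")
    with pytest.raises(ValueError):
        compare_methods({"a": np.ones(5), "b": np.ones(5)}, "missing")


def test_summary_matches_reported_pattern():
    s = summarize_scores([5, 3, 5, 4, 5])
    assert s == {"min": 3.0, "median": 5.0, "max": 5.0}
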