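"""Hybrid registration: self/shift oracles, refinement, composition, QC."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from doseup.ctio import to_eval_uint8
from doseup.features import GradientHistogramExtractor
from doseup.registration import (DisplacementField, RegistrationConfig,
                                 compose_and_warp, extract_patch_features,
                                 feature_refine, global_align, landmark_error,
                                 registration_quality)


def _textured(shape=(128, 128), seed=1, scale=3.0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), scale)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="module")
def extractor():
    return GradientHistogramExtractor(14, stride=7)


def test_config_defaults_and_validation():
    cfg = RegistrationConfig()
    assert cfg.pyramid_iterations == (100, 70, 20)
    assert cfg.feature_patch_size == 14
    assert cfg.feature_dim == 1024
    assert cfg.refine_iterations == 1000
    assert cfg.refine_lr == 3.0
    assert cfg.smooth_weight == 2.0
    with pytest.raises(ValueError):
        RegistrationConfig(pyramid_iterations=(0, 1, 1)).validate()
    with pytest.raises(ValueError, match="mask_mode"):
        RegistrationConfig(mask_mode="bogus").validate()


def test_self_registration_returns_near_zero_field():
    img = _textured()
    warped, field = global_align(img, img, RegistrationConfig())
    assert np.abs(field.vectors).mean() < 0.1


def test_constant_images_yield_identity_with_warning():
    const = np.full((64, 64), 0.5)
    with pytest.warns(UserWarning, match="constant"):
        warped, field = global_align(const, const)
    assert np.abs(field.vectors).max() == 0.0


def test_pure_translation_recovered():
    """A 3-px shift of a textured slice is recovered to within 0.5 px."""
    img = _textured(seed=5)
    moving = np.roll(img, 3, axis=0)  # moving(r) = img(r-3) -> u = +3 rows
    warped, field = global_align(img, moving, RegistrationConfig())
    inner = field.vectors[20:-20, 20:-20]
    assert abs(inner[..., 0].mean() - 3.0) < 0.5
    assert abs(inner[..., 1].mean()) < 0.5


def test_identical_features_refine_to_zero(extractor):
    img = _textured()
    ff = extract_patch_features(img, extractor)
    field = feature_refine(ff, ff, None, RegistrationConfig(),
                           image_shape=img.shape, stride=extractor.stride)
    assert np.abs(field.vectors).max() < 0.1 * extractor.patch_size


def test_discrete_shift_recovered(extractor):
    """Features shifted by one node come back as ~one-node displacement
    on at least 90% of interior nodes (error < 0.25 patch)."""
    img = _textured(seed=2)
    ff = extract_patch_features(img, extractor)
    mf = np.roll(ff, 1, axis=0)   # moving node i holds fixed node i-1
    field = feature_refine(ff, mf, None, RegistrationConfig(),
                           image_shape=img.shape, stride=extractor.stride)
    interior = field.vectors[14:-14, 14:-14]
    err = np.abs(interior[..., 0] - extractor.stride)
    assert (err < 0.25 * extractor.patch_size).mean() >= 0.9


def test_large_smooth_weight_flattens_field(extractor):
    img = _textured(seed=3)
    ff = extract_patch_features(img, extractor)
    mf = np.roll(ff, 1, axis=0)
    base = feature_refine(ff, mf, None,
                          RegistrationConfig(refine_iterations=200, gate_threshold=0.0),
                          image_shape=img.shape, stride=extractor.stride)
    stiff = feature_refine(ff, mf, None,
                           RegistrationConfig(refine_iterations=200,
                                              smooth_weight=1e6, gate_threshold=0.0),
                           image_shape=img.shape, stride=extractor.stride)
    assert stiff.vectors[..., 0].var() < 1e-4 * max(base.vectors[..., 0].var(), 1e-12) \
        or stiff.vectors[..., 0].var() < 1e-4


def test_refine_rejects_bad_inputs(extractor):
    ff = np.zeros((5, 5, 8))
    with pytest.raises(ValueError, match="search window"):
        feature_refine(ff, ff, None, RegistrationConfig(search_window=4))
    bad = ff.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        feature_refine(ff, bad, None, RegistrationConfig(search_window=1))


def test_threshold_mask_freezes_air_region():
    """With mask_mode='threshold', the refinement field outside the body
    (air) stays at its initialization (zero)."""
    from doseup.registration import build_rpr
    img = np.zeros((128, 128))
    img[30:100, 30:100] = _textured((70, 70), seed=8)
    moving = np.roll(img, 2, axis=1)
    cfg = RegistrationConfig(mask_mode="threshold", refine_iterations=50)
    rpr, comp, qc = build_rpr(img, moving, cfg)
    assert np.isfinite(comp.vectors).all()
    assert rpr.shape == img.shape


def test_compose_identity_and_translation_group():
    img = _textured(seed=4)
    g = DisplacementField(np.zeros((128, 128, 2)))
    g.vectors[..., 0] = 2.0
    zero = DisplacementField.zero((128, 128))
    warped_direct = g.warp(img)
    rpr, comp = compose_and_warp(img, g, zero)
    assert (rpr == warped_direct).all()           # refine = 0 -> bit-equal
    # two pure translations compose to their sum
    r = DisplacementField(np.zeros((128, 128, 2)))
    r.vectors[..., 1] = 3.0
    _, comp2 = compose_and_warp(img, g, r)
    assert np.allclose(comp2.vectors[..., 0], 2.0)
    assert np.allclose(comp2.vectors[..., 1], 3.0)


def test_single_pass_close_to_two_pass():
    img = _textured(seed=6)
    rng = np.random.default_rng(0)
    gv = np.stack([gaussian_filter(rng.standard_normal((128, 128)), 10) for _ in range(2)], -1)
    rv = np.stack([gaussian_filter(rng.standard_normal((128, 128)), 10) for _ in range(2)], -1)
    g = DisplacementField(3.0 * gv / np.abs(gv).max())
    r = DisplacementField(2.0 * rv / np.abs(rv).max())
    rpr, comp = compose_and_warp(img, g, r)
    two_pass = r.warp(g.warp(img))
    assert np.abs(rpr - two_pass).mean() < 0.02   # interpolation-order difference


def test_quality_identity_and_offset():
    img = to_eval_uint8(_textured(seed=7))
    qc = registration_quality(img, img)
    assert qc["ncc"] == pytest.approx(1.0)
    assert qc["ssim"] == pytest.approx(1.0)
    assert qc["gradient_error"] == 0.0
    img = (img * 0.7).astype(np.uint8)  # leave headroom so +10 cannot clip
    shifted = (img + 10).astype(np.uint8)
    qc2 = registration_quality(img, shifted)
    assert qc2["ncc"] == pytest.approx(1.0, abs=1e-6)
    assert qc2["gradient_error"] == pytest.approx(0.0, abs=1e-9)
    const = np.full((32, 32), 9, np.uint8)
    qc3 = registration_quality(const, const)
    assert qc3["ncc"] is None and qc3["flags"]


def test_quality_matches_bruteforce():
    rng = np.random.default_rng(11)
    a = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    b = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    qc = registration_quality(a, b)
    af, bf = a.astype(float), b.astype(float)
    ncc = (((af - af.mean()) * (bf - bf.mean())).sum()
           / np.sqrt(((af - af.mean()) ** 2).sum() * ((bf - bf.mean()) ** 2).sum()))
    assert qc["ncc"] == pytest.approx(ncc, rel=1e-9)
    ge = 0.5 * (np.abs(np.diff(af, axis=0) - np.diff(bf, axis=0)).mean()
                + np.abs(np.diff(af, axis=1) - np.diff(bf, axis=1)).mean())
    assert qc["gradient_error"] == pytest.approx(ge, rel=1e-9)
    # SSIM against an independent gaussian-window implementation
    from scipy.ndimage import gaussian_filter as gf
    c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
    mu_a, mu_b = gf(af, 1.5, truncate=3.5), gf(bf, 1.5, truncate=3.5)
    va = gf(af * af, 1.5, truncate=3.5) - mu_a ** 2
    vb = gf(bf * bf, 1.5, truncate=3.5) - mu_b ** 2
    cov = gf(af * bf, 1.5, truncate=3.5) - mu_a * mu_b
    ssim = (((2 * mu_a * mu_b + c1) * (2 * cov + c2))
            / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2))).mean()
    assert qc["ssim"] == pytest.approx(ssim, rel=1e-9)


def test_landmark_error_identity_baseline():
    pts = np.array([[10.0, 10.0], [20.0, 30.0]])
    moved = pts + np.array([1.0, -2.0])
    assert landmark_error(None, pts, moved) == pytest.approx(np.sqrt(5.0))
    field = DisplacementField(np.zeros((64, 64, 2)))
    field.vectors[..., 0] = 1.0
    field.vectors[..., 1] = -2.0
    assert landmark_error(field, pts, moved) == pytest.approx(0.0, abs=1e-9)
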