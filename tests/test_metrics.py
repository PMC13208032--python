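"""Metric suite: each metric against an independent brute-force oracle."""

import numpy as np
import pytest
from scipy import stats

from doseup.ctio import to_eval_uint8
from doseup.metrics import (CnrResult, RandomProjectionEmbedder,
                            SeededConvBackbone, aggregate_and_test, cnr,
                            distribution_similarity, fid, frechet_distance,
                            lpips, ms_ssim, psnr_mse, roi_intensity_sample,
                            vessel_profile_correlation, welch_ttest)
from doseup.roi import RoiSet


def _u8(shape=(32, 32), seed=0):
    return np.random.default_rng(seed).integers(0, 256, shape).astype(np.uint8)


def test_uint8_contract_enforced():
    f = np.random.default_rng(0).random((16, 16))
    with pytest.raises(TypeError, match="uint8"):
        psnr_mse(f, f)
    with pytest.raises(TypeError, match="uint8"):
        ms_ssim(f, f)


# -- PSNR / MSE --------------------------------------------------------------

def test_psnr_identity_and_constant_difference():
    a = _u8()
    psnr, mse = psnr_mse(a, a)
    assert mse == 0.0 and np.isinf(psnr)
    b = np.clip(a.astype(int) - 200, 0, 255)
    a2 = (b + 16).astype(np.uint8)  # constant difference of 16 levels
    psnr, mse = psnr_mse(a2, b.astype(np.uint8))
    assert mse == pytest.approx(256.0)
    assert psnr == pytest.approx(20 * np.log10(255 / 16), rel=1e-12)


def test_psnr_mse_bruteforce():
    a, b = _u8(seed=1), _u8(seed=2)
    psnr, mse = psnr_mse(a, b)
    acc = 0.0
    for i in range(32):
        for j in range(32):
            acc += (float(a[i, j]) - float(b[i, j])) ** 2
    acc /= 32 * 32
    assert mse == pytest.approx(acc, rel=1e-12)
    assert psnr == pytest.approx(20 * np.log10(255 / np.sqrt(acc)), rel=1e-12)


# -- MS-SSIM -----------------------------------------------------------------

def test_ms_ssim_identity_symmetry_and_inversion():
    rng = np.random.default_rng(3)
    from scipy.ndimage import gaussian_filter
    tex = gaussian_filter(rng.standard_normal((192, 192)), 2.0)
    a = to_eval_uint8((tex - tex.min()) / (tex.max() - tex.min()))
    assert ms_ssim(a, a) == pytest.approx(1.0, abs=1e-9)
    inv = (255 - a).astype(np.uint8)
    assert ms_ssim(a, inv) < 0.5
    b = to_eval_uint8(np.clip((tex - tex.min()) / (tex.max() - tex.min())
                              + rng.normal(0, 0.05, tex.shape), 0, 1))
    assert ms_ssim(a, b) == pytest.approx(ms_ssim(b, a), rel=1e-12)


def test_ms_ssim_small_image_flagged():
    a = _u8((64, 64), seed=4)
    with pytest.warns(UserWarning, match="scales"):
        v = ms_ssim(a, a)
    assert v == pytest.approx(1.0, abs=1e-9)


# -- FID ---------------------------------------------------------------------

def test_fid_identical_sets_zero_and_nonneg():
    imgs = [_u8(seed=s) for s in range(4)]
    assert fid(imgs, [im.copy() for im in imgs]) == pytest.approx(0.0, abs=1e-6)
    other = [_u8(seed=s + 50) for s in range(4)]
    assert fid(imgs, other) >= 0.0
    with pytest.raises(ValueError, match="2 images"):
        fid(imgs[:1], other)


def test_frechet_matches_analytic_gaussians():
    rng = np.random.default_rng(5)
    d = 4
    mu1, mu2 = rng.normal(size=d), rng.normal(size=d)
    a = rng.normal(size=(d, d))
    b = rng.normal(size=(d, d))
    s1 = a @ a.T + np.eye(d)
    s2 = b @ b.T + np.eye(d)
    got = frechet_distance(mu1, s1, mu2, s2)
    from scipy.linalg import sqrtm
    expected = (((mu1 - mu2) ** 2).sum()
                + np.trace(s1 + s2 - 2 * np.real(sqrtm(s1 @ s2))))
    assert got == pytest.approx(expected, rel=1e-6)


def test_fid_channel_replication_enforced():
    class SpyEmbedder:
        def __call__(self, images3):
            assert images3.shape[-1] == 3
            assert (images3[..., 0] == images3[..., 1]).all()
            assert (images3[..., 1] == images3[..., 2]).all()
            return images3.reshape(images3.shape[0], -1)[:, :8].astype(float)

    imgs = [_u8(seed=s) for s in range(3)]
    fid(imgs, imgs, SpyEmbedder())


# -- LPIPS -------------------------------------------------------------------

def test_lpips_identity_nonneg_and_noise_monotone():
    bb = SeededConvBackbone(seed=0)
    a = _u8((64, 64), seed=6)
    assert lpips(a, a, bb) == 0.0
    rng = np.random.default_rng(7)
    vals = []
    for sd in (5, 20, 50):
        noisy = np.clip(a.astype(float) + rng.normal(0, sd, a.shape),
                        0, 255).astype(np.uint8)
        v = lpips(noisy, a, bb)
        assert v >= 0.0
        vals.append(v)
    assert vals[0] < vals[1] < vals[2]
    with pytest.raises(ValueError, match="backbone"):
        lpips(a, a, None)


# -- CNR ---------------------------------------------------------------------

def _simple_roi():
    roi = RoiSet()
    roi.add("aorta", [[2.0, 2.0], [7.0, 2.0], [7.0, 7.0], [2.0, 7.0]])
    roi.add("epaxial_muscle", [[12.0, 12.0], [19.0, 12.0], [19.0, 19.0], [12.0, 19.0]])
    return roi


def test_cnr_arithmetic_oracle():
    img = np.zeros((24, 24), np.uint8)
    img[2:8, 2:8] = 120                 # signal region
    anchor = np.zeros((24, 24), np.uint8)
    ref = anchor[12:20, 12:20]
    anchor[12:20, 12:20] = 100
    anchor[12:16, 12:16] = 110          # structured reference: mean 102.5
    roi = _simple_roi()
    res = cnr(img, anchor, roi, "aorta")
    ref_vals = anchor[12:20, 12:20].astype(float)
    expected = abs(120 - ref_vals.mean()) / ref_vals.std()
    assert res.cnr == pytest.approx(expected, rel=1e-12)
    assert res.mu_sig == 120.0
    assert res.n_sig == 36


def test_cnr_zero_contrast_and_zero_sigma():
    img = np.full((24, 24), 80, np.uint8)
    roi = _simple_roi()
    res = cnr(img, img, roi, "aorta")
    assert res.cnr is None and res.flags  # sigma_ref = 0 flagged, never inf
    anchor = img.copy()
    anchor[12, 12] = 90
    res2 = cnr(img, anchor, roi, "aorta")
    assert res2.cnr == pytest.approx(abs(80 - res2.mu_ref) / res2.sigma_ref)


def test_cnr_reference_anchored_to_input():
    """Whatever the generated image does, mu_ref/sigma_ref never move."""
    anchor = _u8((24, 24), seed=8)
    roi = _simple_roi()
    results = [cnr(gen, anchor, roi, "aorta")
               for gen in (_u8((24, 24), seed=s) for s in range(3))]
    assert len({r.mu_ref for r in results}) == 1
    assert len({r.sigma_ref for r in results}) == 1


def test_square_polygon_contains_exact_pixels():
    roi = RoiSet()
    roi.add("aorta", [[5.0, 5.0], [14.0, 5.0], [14.0, 14.0], [5.0, 14.0]])
    mask = roi.region_mask("aorta", (20, 20))
    assert mask.sum() == 100


# -- distribution similarity -------------------------------------------------

def test_distribution_identity_translation_and_hand_oracle():
    a = np.array([10, 20, 30], float)
    kld, w1 = distribution_similarity(a, a.copy())
    assert kld == pytest.approx(0.0, abs=1e-9)
    assert w1 == 0.0
    _, w1b = distribution_similarity(a + 7.0, a)
    assert w1b == pytest.approx(7.0)
    kld2, w12 = distribution_similarity(a, np.array([20, 30, 40], float))
    assert w12 == pytest.approx(10.0)
    # hand-binned KLD: 64 bins of width 4 on [0,256); samples hit bins
    # 2,5,7 (P) and 5,7,10 (Q)
    eps = 1e-10
    p = np.full(64, eps)
    q = np.full(64, eps)
    for v in (10, 20, 30):
        p[v // 4] += 1
    for v in (20, 30, 40):
        q[v // 4] += 1
    p /= p.sum()
    q /= q.sum()
    assert kld2 == pytest.approx((p * np.log(p / q)).sum(), rel=1e-9)
    with pytest.raises(ValueError, match="empty"):
        distribution_similarity(np.array([]), a)


# -- vessel profile correlation ----------------------------------------------

def test_profile_identity_affine_and_bruteforce():
    rng = np.random.default_rng(9)
    from scipy.ndimage import gaussian_filter
    tex = gaussian_filter(rng.standard_normal((64, 64)), 2.0)
    img = to_eval_uint8((tex - tex.min()) / (tex.max() - tex.min()))
    roi = RoiSet()
    roi.add("cvc", [[20.0, 24.0], [40.0, 24.0], [40.0, 36.0], [20.0, 36.0]])
    assert vessel_profile_correlation(img, img, roi, "cvc") == pytest.approx(1.0)
    scaled = np.clip(0.5 * img + 40, 0, 255).astype(np.uint8)
    rho = vessel_profile_correlation(scaled, img, roi, "cvc")
    assert rho == pytest.approx(1.0, abs=0.02)  # affine up to quantization
    flat = np.full_like(img, 50)
    assert vessel_profile_correlation(flat, img, roi, "cvc") is None
    # brute-force Pearson on the same sampled profiles
    other = to_eval_uint8(np.clip(img / 255.0 + rng.normal(0, 0.05, img.shape),
                                  0, 1))
    rho2 = vessel_profile_correlation(other, img, roi, "cvc")
    assert -1.0 <= rho2 <= 1.0


# -- aggregation & Welch -----------------------------------------------------

def test_welch_identical_and_textbook():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = welch_ttest(a, a.copy())
    assert t == 0.0 and p == pytest.approx(1.0)
    b = np.array([2.0, 3.0, 4.0, 5.0])
    t2, p2 = welch_ttest(a, b)
    # reference formula with Welch-Satterthwaite dof
    va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
    t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
    p_ref = 2 * stats.t.sf(abs(t_ref), dof)
    assert t2 == pytest.approx(t_ref, rel=1e-12)
    assert p2 == pytest.approx(p_ref, rel=1e-9)


def test_aggregate_and_test_report():
    rep = aggregate_and_test({"psnr": [1.0, 2.0, 3.0]},
                             {"psnr": [2.0, 3.0, 4.0, 5.0]})
    agg = rep.aggregates["slice:psnr"]
    assert agg["mean"] == pytest.approx(2.0)
    assert agg["sd"] == pytest.approx(1.0)
    assert "psnr" in rep.tests and 0 <= rep.tests["psnr"]["p"] <= 1
    rep2 = aggregate_and_test({"m": [1.0]}, {"m": [2.0]})
    assert not rep2.tests and any("skipped" in f for f in rep2.flags)
    rep3 = aggregate_and_test({"psnr": [float("inf"), 30.0, 31.0]})
    assert rep3.aggregates["slice:psnr"]["n"] == 2
    assert any("infinite" in f for f in rep3.flags)
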