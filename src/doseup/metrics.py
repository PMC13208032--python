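"""Evaluation suite: reference-anchored fidelity, distributional quality,
region-level contrast and reliability validation.

Every metric operates on 8-bit grayscale evaluation images (the quantized
PNG convention); passing floating-point unit-domain images is a contract
violation and raises ``TypeError``. Grayscale images are replicated to
exactly three identical channels at the embedder/backbone boundary for
FID and LPIPS, which are defined on RGB inputs.

Metrics:

* PSNR / MSE against the registration-based pseudo-reference (RPR), with
  ``PSNR = 20 log10(255 / sqrt(MSE))`` and an ``inf`` sentinel for MSE = 0
  (flagged and excluded from means).
* MS-SSIM, 5 dyadic scales with the conventional per-scale weights
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), Gaussian window sigma 1.5,
  K1 = 0.01, K2 = 0.03; negative contrast-structure terms are clamped at
  zero; images too small for 5 scales are scored with fewer scales
  (renormalized weights) under a warning.
* FID on pluggable embeddings: Frechet distance between Gaussian fits,
  matrix square root by symmetric eigendecomposition with negative
  eigenvalues clamped to zero.
* LPIPS-style perceptual distance on a pluggable convolutional backbone:
  per-layer channel-normalized feature differences, spatially averaged,
  layer-summed.
* CNR with the input-anchored protocol: the signal mean comes from the
  evaluated image, while the reference-tissue mean and standard deviation
  (epaxial muscle) are always measured on the *input* image, so a model
  cannot inflate CNR by suppressing reference variance.
* ROI intensity-distribution similarity: KL divergence over 64-bin
  histograms on [0, 255] with additive 1e-10 smoothing (P = generated,
  Q = RPR), and the 1-D Wasserstein-1 distance via empirical quantiles.
* Vessel profile correlation: Pearson correlation of cross-sectional
  intensity profiles along the region's minor principal axis through its
  centroid, extended to 1.5x the region extent, bilinearly sampled at
  pixel spacing.
* Aggregation as mean (sd) plus Welch's unequal-variance t-test with
  Welch-Satterthwaite degrees of freedom, two-sided, alpha = 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter, map_coordinates

from .roi import REFERENCE_REGION, RoiSet, rasterize_polygons

__all__ = [
    "psnr_mse",
    "ssim_single",
    "ms_ssim",
    "frechet_distance",
    "fid",
    "lpips",
    "cnr",
    "CnrResult",
    "roi_intensity_sample",
    "distribution_similarity",
    "vessel_profile_correlation",
    "welch_ttest",
    "aggregate_and_test",
    "MetricReport",
    "RandomProjectionEmbedder",
    "SeededConvBackbone",
]

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _check_u8(img: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise TypeError(
            f"{name} must be an 8-bit evaluation image (dtype uint8); "
            f"got {arr.dtype} — quantize with ctio.to_eval_uint8 first")
    return arr


def _replicate3(img: np.ndarray) -> np.ndarray:
    """Grayscale (H, W) uint8 -> (H, W, 3) with three identical channels."""
    arr = _check_u8(img, "image")
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return np.repeat(arr[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# reference-anchored fidelity
# ---------------------------------------------------------------------------

def psnr_mse(generated: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """PSNR (dB, I_max = 255) and MSE; identical images give (inf, 0)."""
    g = _check_u8(generated, "generated").astype(np.float64)
    r = _check_u8(reference, "reference").astype(np.float64)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    mse = float(((g - r) ** 2).mean())
    if mse == 0.0:
        return float("inf"), 0.0
    return 20.0 * np.log10(255.0 / np.sqrt(mse)), mse


def _ssim_maps(a: np.ndarray, b: np.ndarray, data_range: float = 255.0,
               sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03):
    """Luminance and contrast-structure maps of the standard SSIM."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a = gaussian_filter(a, sigma, truncate=3.5)
    mu_b = gaussian_filter(b, sigma, truncate=3.5)
    var_a = gaussian_filter(a * a, sigma, truncate=3.5) - mu_a ** 2
    var_b = gaussian_filter(b * b, sigma, truncate=3.5) - mu_b ** 2
    cov = gaussian_filter(a * b, sigma, truncate=3.5) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def ssim_single(a: np.ndarray, b: np.ndarray) -> float:
    """Single-scale SSIM (Gaussian window sigma 1.5, K1 0.01, K2 0.03)."""
    a8 = _check_u8(a, "a")
    b8 = _check_u8(b, "b")
    if a8.shape != b8.shape:
        raise ValueError("shape mismatch")
    lum, cs = _ssim_maps(a8, b8)
    return float((lum * cs).mean())


def ms_ssim(generated: np.ndarray, reference: np.ndarray) -> float:
    """Multi-scale SSIM over 5 dyadic scales (fewer, flagged, if too small)."""
    a = _check_u8(generated, "generated").astype(np.float64)
    b = _check_u8(reference, "reference").astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    n_scales = len(MS_SSIM_WEIGHTS)
    min_side = min(a.shape)
    # the 11-px Gaussian window must fit at the coarsest scale
    while n_scales > 1 and min_side // (2 ** (n_scales - 1)) < 11:
        n_scales -= 1
    weights = np.asarray(MS_SSIM_WEIGHTS[:n_scales])
    weights = weights / weights.sum()
    if n_scales < len(MS_SSIM_WEIGHTS):
        warnings.warn(
            f"image too small for 5 MS-SSIM scales; using {n_scales} "
            "(renormalized weights)")
    vals = []
    for s in range(n_scales):
        lum, cs = _ssim_maps(a, b)
        if s == n_scales - 1:
            vals.append(max(float((lum * cs).mean()), 0.0))
        else:
            vals.append(max(float(cs.mean()), 0.0))
            a = a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2).mean(axis=(1, 3)) \
                if a.shape[0] % 2 == 0 and a.shape[1] % 2 == 0 else _pool_odd(a)
            b = b.reshape(b.shape[0] // 2, 2, b.shape[1] // 2, 2).mean(axis=(1, 3)) \
                if b.shape[0] % 2 == 0 and b.shape[1] % 2 == 0 else _pool_odd(b)
    return float(np.prod(np.power(vals, weights)))


def _pool_odd(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return x.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# distributional quality
# ---------------------------------------------------------------------------

def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, eigenvalues clamped."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(mu1: np.ndarray, sigma1: np.ndarray,
                     mu2: np.ndarray, sigma2: np.ndarray) -> float:
    """||mu1-mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^(1/2)), clamped to >= 0."""
    a = _sqrtm_psd(sigma1)
    cross = _sqrtm_psd(a @ sigma2 @ a)
    d = float(((mu1 - mu2) ** 2).sum() + np.trace(sigma1) + np.trace(sigma2)
              - 2.0 * np.trace(cross))
    return max(d, 0.0)


class RandomProjectionEmbedder:
    """Deterministic test embedder: seeded Gaussian random projection.

    Stands in for a pretrained Inception-V3 feature extractor in hermetic
    runs; the projection matrix is drawn once from a fixed seed for the
    first input geometry seen.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._proj: np.ndarray | None = None

    def __call__(self, images3: np.ndarray) -> np.ndarray:
        arr = np.asarray(images3, dtype=np.float64) / 255.0  # (N, H, W, 3)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError("embedder expects (N, H, W, 3) images")
        flat = arr.reshape(arr.shape[0], -1)
        if self._proj is None or self._proj.shape[0] != flat.shape[1]:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((flat.shape[1], self.dim)) / np.sqrt(flat.shape[1])
        return flat @ self._proj


def fid(reference_set: list[np.ndarray], generated_set: list[np.ndarray],
        embedder=None) -> float:
    """Frechet distance between embedded image sets (>= 2 images each)."""
    if len(reference_set) < 2 or len(generated_set) < 2:
        raise ValueError("FID needs at least 2 images per set (covariance)")
    embedder = embedder or RandomProjectionEmbedder()
    ref3 = np.stack([_replicate3(im) for im in reference_set])
    gen3 = np.stack([_replicate3(im) for im in generated_set])
    assert (ref3[..., 0] == ref3[..., 1]).all() and (ref3[..., 1] == ref3[..., 2]).all()
    er = np.asarray(embedder(ref3), dtype=np.float64)
    eg = np.asarray(embedder(gen3), dtype=np.float64)
    if not (np.isfinite(er).all() and np.isfinite(eg).all()):
        raise ValueError("non-finite embeddings")
    mu_r, mu_g = er.mean(0), eg.mean(0)
    sr = np.cov(er, rowvar=False)
    sg = np.cov(eg, rowvar=False)
    return frechet_distance(mu_r, sr, mu_g, sg)


class SeededConvBackbone:
    """Deterministic test perceptual backbone: a fixed random conv stack.

    Three stride-2 valid convolutions with ReLU, filters drawn once from a
    seed. Stands in for a pretrained AlexNet feature extractor.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 16), k: int = 5):
        rng = np.random.default_rng(seed)
        self.filters = []
        cin = 3
        for cout in channels:
            w = rng.standard_normal((cout, cin, k, k)) / np.sqrt(cin * k * k)
            self.filters.append(w)
            cin = cout

    def __call__(self, img3: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(img3, dtype=np.float64)  # (3, H, W) in [0,1]
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError("backbone expects a (3, H, W) image")
        feats = []
        for w in self.filters:
            k = w.shape[-1]
            sw = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))[:, ::2, ::2]
            x = np.einsum("chwij,ocij->ohw", sw, w, optimize=True)
            x = np.maximum(x, 0.0)
            feats.append(x)
        return feats


def lpips(generated: np.ndarray, reference: np.ndarray, backbone=None) -> float:
    """Perceptual distance: channel-normalized per-layer feature differences."""
    if backbone is None:
        raise ValueError(
            "no perceptual backbone given: pass a pretrained backbone adapter "
            "or metrics.SeededConvBackbone for hermetic evaluation")
    g3 = _replicate3(generated).astype(np.float64).transpose(2, 0, 1) / 255.0
    r3 = _replicate3(reference).astype(np.float64).transpose(2, 0, 1) / 255.0
    assert (g3[0] == g3[1]).all() and (g3[1] == g3[2]).all()
    total = 0.0
    for fg, fr in zip(backbone(g3), backbone(r3)):
        ng = fg / np.maximum(np.linalg.norm(fg, axis=0, keepdims=True), 1e-10)
        nr = fr / np.maximum(np.linalg.norm(fr, axis=0, keepdims=True), 1e-10)
        total += float(((ng - nr) ** 2).sum(axis=0).mean())
    return total


# ---------------------------------------------------------------------------
# region-level contrast
# ---------------------------------------------------------------------------

@dataclass
class CnrResult:
    cnr: float | None
    mu_sig: float
    mu_ref: float
    sigma_ref: float
    n_sig: int
    n_ref: int
    flags: list[str] = field(default_factory=list)


def cnr(target_image: np.ndarray, input_anchor_image: np.ndarray,
        roi: RoiSet, region: str) -> CnrResult:
    """Input-anchored contrast-to-noise ratio of a region.

    ``mu_sig`` is measured on ``target_image`` inside the region's pooled
    polygons; ``mu_ref`` and ``sigma_ref`` are measured on
    ``input_anchor_image`` inside the epaxial-muscle reference polygons.
    """
    tgt = _check_u8(target_image, "target_image").astype(np.float64)
    anc = _check_u8(input_anchor_image, "input_anchor_image").astype(np.float64)
    sig_mask = roi.region_mask(region, tgt.shape)
    ref_mask = rasterize_polygons(roi.reference_polygons, anc.shape)
    if not sig_mask.any():
        raise ValueError(f"region {region!r} rasterizes to an empty mask")
    if not ref_mask.any():
        raise ValueError(f"reference region {REFERENCE_REGION!r} is empty")
    mu_sig = float(tgt[sig_mask].mean())
    mu_ref = float(anc[ref_mask].mean())
    sigma_ref = float(anc[ref_mask].std())
    if sigma_ref == 0.0:
        return CnrResult(None, mu_sig, mu_ref, 0.0, int(sig_mask.sum()),
                         int(ref_mask.sum()), ["sigma_ref = 0: CNR undefined"])
    return CnrResult(abs(mu_sig - mu_ref) / sigma_ref, mu_sig, mu_ref, sigma_ref,
                     int(sig_mask.sum()), int(ref_mask.sum()))


def roi_intensity_sample(image: np.ndarray, roi: RoiSet, region: str) -> np.ndarray:
    """Pooled uint8 intensities inside a region's polygons."""
    img = _check_u8(image, "image")
    mask = roi.region_mask(region, img.shape)
    return img[mask]


def distribution_similarity(generated_sample: np.ndarray,
                            rpr_sample: np.ndarray) -> tuple[float, float]:
    """(KLD, Wasserstein-1) between ROI intensity samples.

    KLD uses 64-bin histograms on [0, 255] with 1e-10 additive smoothing,
    direction P = generated, Q = RPR. W1 is the empirical
    quantile-function integral of the raw samples.
    """
    g = np.asarray(generated_sample, dtype=np.float64).ravel()
    r = np.asarray(rpr_sample, dtype=np.float64).ravel()
    if g.size == 0 or r.size == 0:
        raise ValueError("empty intensity sample")
    eps = 1e-10
    hp, _ = np.histogram(g, bins=64, range=(0, 256))
    hq, _ = np.histogram(r, bins=64, range=(0, 256))
    p = hp + eps
    q = hq + eps
    p = p / p.sum()
    q = q / q.sum()
    kld = float((p * np.log(p / q)).sum())
    w1 = float(stats.wasserstein_distance(g, r))
    return kld, w1


def vessel_profile_correlation(generated: np.ndarray, rpr: np.ndarray,
                               roi: RoiSet, region: str) -> float | None:
    """Pearson correlation of cross-sectional intensity profiles.

    The profile line passes through the region centroid along the minor
    principal axis of the rasterized region, extended to 1.5x the region's
    extent along that axis, sampled at pixel spacing with bilinear
    interpolation on both images. Returns ``None`` (flagged missing) for a
    zero-variance profile.
    """
    g = _check_u8(generated, "generated").astype(np.float64)
    r = _check_u8(rpr, "rpr").astype(np.float64)
    mask = roi.region_mask(region, g.shape)
    if not mask.any():
        raise ValueError(f"region {region!r} rasterizes to an empty mask")
    pts = np.argwhere(mask).astype(np.float64)  # (n, 2) (row, col)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T) if len(pts) > 1 else np.eye(2)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    minor = vecs[:, 0]  # eigenvector of the smaller eigenvalue
    proj = (pts - centroid) @ minor
    extent = float(proj.max() - proj.min()) if len(pts) > 1 else 1.0
    half = 0.75 * max(extent, 2.0)  # 1.5x extent total length
    n = max(int(np.ceil(2 * half)) + 1, 5)
    ts = np.linspace(-half, half, n)
    line = centroid[None, :] + ts[:, None] * minor[None, :]
    prof_g = map_coordinates(g, [line[:, 0], line[:, 1]], order=1, mode="nearest")
    prof_r = map_coordinates(r, [line[:, 0], line[:, 1]], order=1, mode="nearest")
    if prof_g.std() < 1e-12 or prof_r.std() < 1e-12:
        return None
    return float(np.corrcoef(prof_g, prof_r)[0, 1])


# ---------------------------------------------------------------------------
# aggregation & statistics
# ---------------------------------------------------------------------------

def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test needs >= 2 samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class MetricReport:
    """Per-slice and per-ROI records plus aggregates and tests."""

    per_slice: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_roi: pd.DataFrame = field(default_factory=pd.DataFrame)
    dataset_level: dict = field(default_factory=dict)
    aggregates: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def summarize(self):
        """(Re)compute mean (sd) aggregates from the per-item records.

        Infinite PSNR sentinels are excluded from means and counted in
        ``flags``.
        """
        agg = {}
        for df, tag in ((self.per_slice, "slice"), (self.per_roi, "roi")):
            if df.empty:
                continue
            for col in df.columns:
                if not np.issubdtype(df[col].dtype, np.number):
                    continue
                vals = df[col].to_numpy(dtype=float)
                n_inf = int(np.isinf(vals).sum())
                vals = vals[np.isfinite(vals)]
                if n_inf:
                    self.flags.append(f"{tag}:{col}: {n_inf} infinite values excluded")
                if len(vals):
                    agg[f"{tag}:{col}"] = {"mean": float(np.mean(vals)),
                                           "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                                           "n": int(len(vals))}
        self.aggregates = agg
        return self

    def to_json(self, path: str):
        doc = {
            "dataset_level": self.dataset_level,
            "aggregates": self.aggregates,
            "tests": self.tests,
            "flags": self.flags,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)

    def to_csv(self, slice_path: str, roi_path: str | None = None):
        self.per_slice.to_csv(slice_path, index=False)
        if roi_path is not None:
            self.per_roi.to_csv(roi_path, index=False)


def aggregate_and_test(records_a: dict[str, list[float]],
                       records_b: dict[str, list[float]] | None = None,
                       alpha: float = 0.05) -> MetricReport:
    """Aggregate per-item metric records, optionally Welch-testing A vs B."""
    report = MetricReport(per_slice=pd.DataFrame(records_a))
    report.summarize()
    if records_b is not None:
        for key in records_a:
            if key not in records_b:
                continue
            a = np.asarray(records_a[key], dtype=float)
            b = np.asarray(records_b[key], dtype=float)
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if len(a) < 2 or len(b) < 2:
                report.flags.append(f"test {key}: skipped (group size < 2)")
                continue
            t, p = welch_ttest(a, b)
            report.tests[key] = {"t": t, "p": p, "significant": bool(p < alpha)}
    return report
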