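"""Registration-based pseudo-reference (RPR) construction.

Weakly aligned scan pairs (a fixed low-dose or pre-contrast slice and a
moving full-dose slice of the same subject) are turned into supervisory
pseudo-references in two stages:

1. **Global alignment** — deformable registration over a 3-level
   multi-resolution pyramid with a (100, 70, 20) iteration schedule.
   Backends are pluggable; the built-in default is a multi-resolution
   diffeomorphic-demons backend (SimpleITK) with histogram matching to
   absorb the cross-dose intensity shift, and a mutual-information-driven
   B-spline free-form-deformation backend is provided for strongly
   multi-modal pairs. An adapter slot accepts an external symmetric
   diffeomorphic (SyN) implementation when one is installed.
2. **Feature-level refinement** — contrast-robust patch descriptors are
   matched by a two-phase instance optimization: a discrete correlation
   search over a bounded window provides a smoothed (convex-relaxed)
   initialization, then Adam refines a control-point displacement field
   (default 1000 iterations, learning rate 3.0, diffusion regularizer
   weight 2.0). An optional mask freezes the field outside the region of
   interest.

The two fields are composed and the moving image is resampled **once**
through the composite field; the result is the RPR slice. Alignment QC
reports NCC, SSIM and gradient error against the fixed image.

Field convention (pull-back): a field ``u`` on the fixed grid means
``warped(x) = moving(x + u(x))``; composition of a global field ``g``
with a refinement ``r`` is ``(g ∘ r)(x) = g(x + r(x)) + r(x)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter, map_coordinates

from .features import FeatureExtractor, GradientHistogramExtractor

__all__ = [
    "DisplacementField",
    "RegistrationConfig",
    "global_align",
    "extract_patch_features",
    "feature_refine",
    "compose_and_warp",
    "registration_quality",
    "landmark_error",
    "build_rpr",
    "register_backend",
]


@dataclass
class DisplacementField:
    """Dense 2-D displacement field on the fixed-image grid, (dy, dx) px."""

    vectors: np.ndarray  # (H, W, 2)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 3 or self.vectors.shape[-1] != 2:
            raise ValueError("DisplacementField vectors must have shape (H, W, 2)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("DisplacementField contains non-finite components")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinearly sample the field at (row, col) points."""
        pts = np.asarray(points, dtype=float)
        return np.stack([
            map_coordinates(self.vectors[..., k], [pts[:, 0], pts[:, 1]],
                            order=1, mode="nearest")
            for k in range(2)
        ], axis=1)

    def smoothness(self) -> float:
        """Mean squared forward difference of the field (diagnostic)."""
        v = self.vectors
        dy = v[1:, :, :] - v[:-1, :, :]
        dx = v[:, 1:, :] - v[:, :-1, :]
        return float((dy ** 2).mean() + (dx ** 2).mean())

    def fold_fraction(self) -> float:
        """Fraction of pixels with Jacobian determinant <= 0."""
        dyy, dyx = np.gradient(self.vectors[..., 0])
        dxy, dxx = np.gradient(self.vectors[..., 1])
        det = (1.0 + dyy) * (1.0 + dxx) - dyx * dxy
        return float((det <= 0).mean())

    def warp(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        H, W = self.grid_shape
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        return map_coordinates(np.asarray(image, dtype=np.float64),
                               [rr + self.vectors[..., 0], cc + self.vectors[..., 1]],
                               order=order, mode="nearest")

    @staticmethod
    def zero(shape: tuple[int, int]) -> "DisplacementField":
        return DisplacementField(np.zeros((*shape, 2)))


@dataclass
class RegistrationConfig:
    """Hybrid registration hyperparameters (defaults are the committed ones)."""

    pyramid_iterations: tuple[int, int, int] = (100, 70, 20)
    feature_patch_size: int = 14
    feature_dim: int = 1024
    refine_iterations: int = 1000
    refine_lr: float = 3.0
    smooth_weight: float = 2.0
    mask_mode: str = "none"          # none | threshold | provided
    similarity: str = "mi"           # stage-1 similarity (ffd backend)
    backend: str = "demons"          # demons | ffd_mi | registered adapter name
    search_window: int = 3           # discrete search half-width, control nodes
    feature_stride: int = 7          # control-node spacing, px (half-patch)
    gate_threshold: float = 0.05     # min per-node matching gain to keep a refinement
    demons_smoothing: float = 3.5    # demons displacement-field smoothing sigma, px
    demons_update_smoothing: float = 2.5  # demons update-field smoothing sigma, px

    def validate(self):
        if any(i <= 0 for i in self.pyramid_iterations):
            raise ValueError("pyramid_iterations must be positive")
        for name in ("feature_patch_size", "feature_dim", "refine_iterations",
                     "search_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mask_mode not in ("none", "threshold", "provided"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")


# ---------------------------------------------------------------------------
# stage 1: global deformable alignment
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, callable] = {}


def register_backend(name: str, fn):
    """Register an external stage-1 backend (e.g. an SyN adapter).

    ``fn(fixed, moving, config) -> (H, W, 2) displacement array (dy, dx) px``.
    """
    _BACKENDS[name] = fn


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float32))


def _demons_backend(fixed: np.ndarray, moving: np.ndarray,
                    config: RegistrationConfig) -> np.ndarray:
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    # absorb the cross-dose intensity shift before the intensity-driven demons
    m = sitk.HistogramMatching(m, f, numberOfHistogramLevels=256,
                               numberOfMatchPoints=15, thresholdAtMeanIntensity=False)
    filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    filt.SetSmoothDisplacementField(True)
    filt.SetStandardDeviations(config.demons_smoothing)
    if config.demons_update_smoothing > 0:
        filt.SetSmoothUpdateField(True)
        filt.SetUpdateFieldStandardDeviations(config.demons_update_smoothing)
    shrinks = (4, 2, 1)
    disp = None
    for shrink, iters in zip(shrinks, config.pyramid_iterations):
        if shrink > 1:
            fl = sitk.Shrink(sitk.SmoothingRecursiveGaussian(f, shrink * 0.5), [shrink] * 2)
            ml = sitk.Shrink(sitk.SmoothingRecursiveGaussian(m, shrink * 0.5), [shrink] * 2)
        else:
            fl, ml = f, m
        if disp is None:
            disp = sitk.Image(fl.GetSize(), sitk.sitkVectorFloat64)
            disp.CopyInformation(fl)
        else:
            disp = sitk.Resample(disp, fl, sitk.Transform(), sitk.sitkLinear)
        filt.SetNumberOfIterations(int(iters))
        disp = filt.Execute(fl, ml, disp)
    disp = sitk.Resample(disp, f, sitk.Transform(), sitk.sitkLinear)
    arr = sitk.GetArrayFromImage(disp)  # (H, W, 2) components (dx, dy) physical
    return arr[..., ::-1]  # -> (dy, dx); spacing is 1 so physical == px


def _ffd_mi_backend(fixed: np.ndarray, moving: np.ndarray,
                    config: RegistrationConfig) -> np.ndarray:
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if config.similarity == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    tx = sitk.BSplineTransformInitializer(f, [6, 6])
    reg.SetInitialTransformAsBSpline(tx, inPlace=True, scaleFactors=[1, 2, 4])
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    # the optimizer budget is shared across pyramid levels; the per-level
    # iteration split of the schedule applies to the demons backend
    reg.SetOptimizerAsLBFGS2(numberOfIterations=int(sum(config.pyramid_iterations)))
    reg.Execute(f, m)
    disp = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, f.GetSize(), f.GetOrigin(), f.GetSpacing(),
        f.GetDirection())
    return sitk.GetArrayFromImage(disp)[..., ::-1]


def global_align(fixed: np.ndarray, moving: np.ndarray,
                 config: RegistrationConfig | None = None
                 ) -> tuple[np.ndarray, DisplacementField]:
    """Stage-1 global deformable alignment of a moving onto a fixed slice.

    Returns the warped moving image and the moving-to-fixed displacement
    field. Constant images cannot drive the similarity metric; an identity
    field is returned with a warning.
    """
    config = config or RegistrationConfig()
    config.validate()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: fixed {fixed.shape} vs moving {moving.shape}")
    if fixed.std() < 1e-12 or moving.std() < 1e-12:
        warnings.warn("global_align: constant image, returning identity field")
        fld = DisplacementField.zero(fixed.shape)
        return moving.copy(), fld
    backend = _BACKENDS.get(config.backend)
    if backend is None:
        backend = {"demons": _demons_backend, "ffd_mi": _ffd_mi_backend}.get(config.backend)
    if backend is None:
        warnings.warn(
            f"registration backend {config.backend!r} unavailable; "
            "falling back to built-in diffeomorphic demons")
        backend = _demons_backend
    fld = DisplacementField(backend(fixed, moving, config))
    return fld.warp(moving), fld


# ---------------------------------------------------------------------------
# stage 2: feature-level refinement
# ---------------------------------------------------------------------------

def extract_patch_features(image: np.ndarray,
                           extractor: FeatureExtractor | None = None) -> np.ndarray:
    """Per-patch L2-normalized descriptors as an (Hp, Wp, D) grid."""
    if extractor is None:
        extractor = GradientHistogramExtractor()
    feats = extractor.extract(np.asarray(image, dtype=np.float64))
    if feats.ndim != 3:
        raise ValueError("feature extractor must return an (Hp, Wp, D) grid")
    return feats


def _sample_grid(vol: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sample of an (Hp, Wp, D) grid at fractional (row, col)."""
    out = np.empty(rows.shape + (vol.shape[-1],))
    for d in range(vol.shape[-1]):
        out[..., d] = map_coordinates(vol[..., d], [rows, cols], order=1, mode="nearest")
    return out


def feature_refine(fixed_features: np.ndarray, moving_features: np.ndarray,
                   init_field: DisplacementField | None,
                   config: RegistrationConfig | None = None,
                   mask: np.ndarray | None = None,
                   image_shape: tuple[int, int] | None = None,
                   stride: int | None = None,
                   weight: np.ndarray | None = None) -> DisplacementField:
    """Two-phase instance optimization of a control-point displacement field.

    Phase 1 evaluates descriptor correlation over integer node offsets in a
    bounded window around the initialization and Gaussian-smooths the
    arg-max field (the convex-relaxed initialization). Phase 2 runs Adam on
    the control-point field minimizing feature dissimilarity plus
    ``smooth_weight`` times a diffusion regularizer. Displacements are kept
    in pixels; control nodes are spaced ``stride`` px apart (the feature
    grid's stride; defaults to ``config.feature_stride``); the output field
    is bilinearly upsampled to the pixel grid.

    ``mask`` (pixel grid, boolean) freezes the field to its initialization
    outside the masked region. ``weight`` (node grid, [0, 1]) down-weights
    the data term per node — descriptors from structureless regions carry
    no matching information and should not push the field; low-confidence
    nodes (< 0.5) also keep their initialization through the discrete
    phase.
    """
    config = config or RegistrationConfig()
    config.validate()
    ff, mf = np.asarray(fixed_features), np.asarray(moving_features)
    if ff.shape != mf.shape:
        raise ValueError(f"feature grids differ: {ff.shape} vs {mf.shape}")
    if not (np.isfinite(ff).all() and np.isfinite(mf).all()):
        raise ValueError("NaN/Inf in feature grids")
    Hp, Wp, D = ff.shape
    s = int(stride) if stride is not None else config.feature_stride
    w = config.search_window
    if 2 * w + 1 > min(Hp, Wp):
        raise ValueError(
            f"search window ±{w} nodes exceeds the {Hp}x{Wp} feature grid")
    if image_shape is not None:
        H, W = image_shape
    elif init_field is not None:
        H, W = init_field.grid_shape
    else:
        H, W = Hp * s, Wp * s
    from .features import grid_geometry
    _, _, off_r, off_c, _ = grid_geometry((H, W), config.feature_patch_size, s)
    node_r = off_r + np.arange(Hp) * s
    node_c = off_c + np.arange(Wp) * s

    # initialization at node centers (px)
    if init_field is not None:
        rr, cc = np.meshgrid(np.clip(node_r, 0, H - 1), np.clip(node_c, 0, W - 1),
                             indexing="ij")
        init_px = init_field.sample(np.stack([rr.ravel(), cc.ravel()], 1)).reshape(Hp, Wp, 2)
    else:
        init_px = np.zeros((Hp, Wp, 2))
    base = np.round(init_px / s).astype(int)  # integer node offsets

    wgt = np.ones((Hp, Wp)) if weight is None else np.clip(np.asarray(weight, float), 0, 1)
    if wgt.shape != (Hp, Wp):
        raise ValueError(f"weight grid {wgt.shape} does not match features {(Hp, Wp)}")

    # phase 1: discrete correlation over the bounded search window
    gr, gc = np.mgrid[0:Hp, 0:Wp]
    best_cost = np.full((Hp, Wp), np.inf)
    best_off = np.zeros((Hp, Wp, 2), dtype=int)
    for a in range(-w, w + 1):
        for b in range(-w, w + 1):
            ir = np.clip(gr + base[..., 0] + a, 0, Hp - 1)
            ic = np.clip(gc + base[..., 1] + b, 0, Wp - 1)
            cost = 1.0 - np.einsum("ijd,ijd->ij", ff, mf[ir, ic])
            upd = cost < best_cost
            best_cost = np.where(upd, cost, best_cost)
            best_off[upd] = np.array([a, b])[None, :] + base[upd]
    low_conf = wgt < 0.5
    best_off[low_conf] = base[low_conf]
    disp_nodes = np.stack(
        [gaussian_filter(best_off[..., k].astype(np.float64), 1.0) for k in range(2)], -1)

    # phase 2: Adam instance optimization (displacements in px). The
    # diffusion regularizer is applied by operator splitting: each Adam
    # step on the feature-matching term is followed by Gaussian smoothing
    # of the control field with sigma^2 = smooth_weight / 2 (node units),
    # the convolution equivalent of one implicit diffusion step. In the
    # smooth_weight -> infinity limit the field becomes spatially
    # constant; at 0 the nodes are independent.
    sig = float(np.sqrt(max(config.smooth_weight, 0.0) / 2.0))
    v = disp_nodes * s
    init_pin = init_px.copy()
    pmask = None
    if mask is not None:
        mrr = np.clip(np.round(node_r).astype(int), 0, mask.shape[0] - 1)
        mcc = np.clip(np.round(node_c).astype(int), 0, mask.shape[1] - 1)
        pmask = np.asarray(mask, bool)[np.ix_(mrr, mcc)]
        v[~pmask] = init_pin[~pmask]

    def _smooth(x):
        if sig == 0.0:
            return x.copy()
        return np.stack([gaussian_filter(x[..., k], sig) for k in range(2)], -1)

    # spatial gradients of the moving feature grid (per node-coordinate)
    mf_gy, mf_gx = np.gradient(mf, axis=(0, 1))
    m1 = np.zeros_like(v)
    m2 = np.zeros_like(v)
    b1, b2, eps = 0.9, 0.999, 1e-8
    d = _smooth(v)
    # constant-lr Adam oscillates around the minimum; the returned field is
    # the average of the trailing 20% of iterates (tail averaging)
    tail_start = int(config.refine_iterations * 0.8)
    tail_sum = np.zeros_like(v)
    tail_n = 0
    for t in range(1, config.refine_iterations + 1):
        pr = gr + d[..., 0] / s
        pc = gc + d[..., 1] / s
        gy = _sample_grid(mf_gy, pr, pc)
        gx = _sample_grid(mf_gx, pr, pc)
        gd_r = -np.einsum("ijd,ijd->ij", ff, gy) * wgt / s
        gd_c = -np.einsum("ijd,ijd->ij", ff, gx) * wgt / s
        grad = np.stack([gd_r, gd_c], -1) / (Hp * Wp)
        # diffusion-regularizer gradient: tethers each node to its
        # neighbours, keeping gradient noise from accumulating as a walk
        lap = np.zeros_like(d)
        du = d / s
        lap[:-1] += du[:-1] - du[1:]
        lap[1:] += du[1:] - du[:-1]
        lap[:, :-1] += du[:, :-1] - du[:, 1:]
        lap[:, 1:] += du[:, 1:] - du[:, :-1]
        grad += config.smooth_weight * 2.0 * lap / (Hp * Wp * s)
        grad = _smooth(grad)  # chain rule through the smoothed latent
        m1 = b1 * m1 + (1 - b1) * grad
        m2 = b2 * m2 + (1 - b2) * grad * grad
        # cosine-annealed step (refine_lr is the initial rate): Adam with a
        # constant step of this size orbits the minimum instead of settling
        lr_t = config.refine_lr * 0.5 * (1.0 + np.cos(np.pi * (t - 1)
                                                      / config.refine_iterations))
        step = lr_t * (m1 / (1 - b1 ** t)) / (np.sqrt(m2 / (1 - b2 ** t)) + eps)
        v = v - step
        if pmask is not None:
            v[~pmask] = init_pin[~pmask]
        d = _smooth(v)
        if t > tail_start:
            tail_sum += d
            tail_n += 1
    if tail_n:
        d = tail_sum / tail_n

    # verification gate: a node keeps its refined displacement only if it
    # bought a clear matching gain over the initialization; otherwise it
    # snaps back. Descriptors are band-limited at the node stride, so
    # sub-pixel residuals carry no reliable matching signal — without the
    # gate the refinement would inject interpolation-bias noise on pairs
    # the global stage already aligned.
    def _cost_at(dd):
        pr = np.clip(gr + dd[..., 0] / s, 0, Hp - 1)
        pc = np.clip(gc + dd[..., 1] / s, 0, Wp - 1)
        return 1.0 - np.einsum("ijd,ijd->ij", ff, _sample_grid(mf, pr, pc))

    gain = _cost_at(init_px) - _cost_at(d)
    keep = gain > config.gate_threshold
    if not keep.any():
        d = init_px
    else:
        d = np.where(keep[..., None], d, init_px)
        d = _smooth(d)

    # upsample the node-grid field to the pixel grid
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    pr = np.clip((rr - off_r) / s, 0, Hp - 1)
    pc = np.clip((cc - off_c) / s, 0, Wp - 1)
    out = np.stack([
        map_coordinates(d[..., k], [pr, pc], order=1, mode="nearest") for k in range(2)
    ], -1)
    return DisplacementField(out)


# ---------------------------------------------------------------------------
# composition, warping, QC
# ---------------------------------------------------------------------------

def node_saliency(image: np.ndarray, patch: int, stride: int) -> np.ndarray:
    """Per-node matching confidence from local gradient energy.

    Nodes whose window holds real structure (edges) get weights near 1;
    structureless windows — where descriptors encode only noise — fall
    toward 0. The soft threshold sits at the image's mean node energy.
    """
    from .features import grid_geometry

    img = np.asarray(image, dtype=np.float64)
    nr, nc, _, _, pads = grid_geometry(img.shape, patch, stride)
    padded = np.pad(img, pads, mode="edge")
    gy, gx = np.gradient(gaussian_filter(padded, 1.0))
    mag = np.hypot(gy, gx)
    sc = stride
    energy = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            energy[i, j] = mag[i * sc:i * sc + patch, j * sc:j * sc + patch].mean()
    tau = max(energy.mean(), 1e-12)
    return energy ** 2 / (energy ** 2 + tau ** 2)


def compose_and_warp(moving: np.ndarray, global_field: DisplacementField,
                     refine_field: DisplacementField
                     ) -> tuple[np.ndarray, DisplacementField]:
    """Compose the two stages and resample the moving image once.

    ``composite(x) = global(x + refine(x)) + refine(x)`` — the refinement
    maps fixed-grid points into the globally aligned frame, then the global
    field carries them into the moving frame. The RPR is the moving image
    interpolated a single time through the composite field.
    """
    if global_field.grid_shape != refine_field.grid_shape:
        raise ValueError(
            f"field grids differ: {global_field.grid_shape} vs {refine_field.grid_shape}")
    H, W = global_field.grid_shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    pts = np.stack([(rr + refine_field.vectors[..., 0]).ravel(),
                    (cc + refine_field.vectors[..., 1]).ravel()], 1)
    g_at = global_field.sample(pts).reshape(H, W, 2)
    composite = DisplacementField(g_at + refine_field.vectors)
    return composite.warp(moving), composite


def registration_quality(reference: np.ndarray, aligned: np.ndarray) -> dict:
    """Alignment QC: NCC, single-scale SSIM and mean gradient error.

    NCC is the Pearson correlation of intensities; the gradient error is
    the mean absolute forward-difference gradient disagreement, averaged
    over both axes. Inputs are 8-bit evaluation images.
    """
    from .metrics import ssim_single

    ref = np.asarray(reference, dtype=np.float64)
    ali = np.asarray(aligned, dtype=np.float64)
    if ref.shape != ali.shape:
        raise ValueError("registration_quality: shape mismatch")
    out: dict[str, float | None] = {}
    if ref.std() < 1e-12 or ali.std() < 1e-12:
        out["ncc"] = None
        out["flags"] = ["constant image: NCC undefined"]
    else:
        out["ncc"] = float(np.corrcoef(ref.ravel(), ali.ravel())[0, 1])
        out["flags"] = []
    out["ssim"] = ssim_single(np.asarray(reference), np.asarray(aligned))
    gy_r, gx_r = ref[1:, :] - ref[:-1, :], ref[:, 1:] - ref[:, :-1]
    gy_a, gx_a = ali[1:, :] - ali[:-1, :], ali[:, 1:] - ali[:, :-1]
    out["gradient_error"] = float(
        0.5 * (np.abs(gy_r - gy_a).mean() + np.abs(gx_r - gx_a).mean()))
    return out


def landmark_error(field: DisplacementField | None, fixed_points: np.ndarray,
                   moving_points: np.ndarray) -> float:
    """Mean distance between mapped fixed landmarks and their moving truth.

    ``field`` maps fixed-grid positions into the moving frame (pull-back
    convention); ``None`` scores the unregistered baseline.
    """
    fp = np.asarray(fixed_points, dtype=float)
    mp = np.asarray(moving_points, dtype=float)
    mapped = fp if field is None else fp + field.sample(fp)
    return float(np.linalg.norm(mapped - mp, axis=1).mean())


def build_rpr(fixed: np.ndarray, moving: np.ndarray,
              config: RegistrationConfig | None = None,
              extractor: FeatureExtractor | None = None,
              mask: np.ndarray | None = None
              ) -> tuple[np.ndarray, DisplacementField, dict]:
    """Full hybrid pipeline: global align, feature refine, compose, QC.

    Returns ``(rpr_slice, composite_field, qc)`` where ``qc`` holds NCC /
    SSIM / gradient error of unregistered, global and hybrid stages
    against the fixed slice (computed on 8-bit quantized copies).
    """
    config = config or RegistrationConfig()
    extractor = extractor or GradientHistogramExtractor(
        patch_size=config.feature_patch_size, stride=config.feature_stride)
    if config.mask_mode == "none":
        mask = None
    elif config.mask_mode == "threshold":
        # body/air mask: the -400 HU air threshold lies below the
        # soft-tissue window floor, so on windowed unit-domain slices the
        # operational rule is "above the window floor"
        mask = np.asarray(fixed) > 1e-3
    warped_g, gfield = global_align(fixed, moving, config)
    ff = extract_patch_features(fixed, extractor)
    mf = extract_patch_features(warped_g, extractor)
    wgt = node_saliency(fixed, extractor.patch_size, extractor.stride)
    rfield = feature_refine(ff, mf, None, config, mask=mask,
                            image_shape=fixed.shape, stride=extractor.stride,
                            weight=wgt)
    # refinement was estimated against the globally aligned frame, so its
    # field composes with the global field
    rpr, composite = compose_and_warp(moving, gfield, rfield)
    from .ctio import to_eval_uint8
    f8 = to_eval_uint8(np.clip(fixed, 0, 1))
    qc = {
        "unregistered": registration_quality(f8, to_eval_uint8(np.clip(moving, 0, 1))),
        "global": registration_quality(f8, to_eval_uint8(np.clip(warped_g, 0, 1))),
        "hybrid": registration_quality(f8, to_eval_uint8(np.clip(rpr, 0, 1))),
        "global_field": gfield,  # stage-1 field, so callers need not re-register
    }
    return rpr, composite, qc
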