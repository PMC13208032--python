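"""Synthetic abdominal CT phantom with known dose response and misalignment.

Real triplets of non-contrast (Pre), low-dose (Post40) and full-dose
(Post100) abdominal CT are private clinical data, so this module builds a
controllable stand-in: a 2.5-D phantom whose anatomy is composed of ellipse
primitives on a body ellipse — large moderate-enhancement parenchymal blobs
(liver, spleen, kidney cortex), small high-enhancement vascular disks
(aorta, caudal vena cava, hepatic and portal veins) and a pair of
non-enhancing epaxial muscles that serve as the CNR reference tissue.

Per region the mean attenuation follows a linear dose response

    HU(region, kappa) = baseline(region) + kappa * enhancement(region)

with dose fraction ``kappa`` in [0, 1] (0 = Pre, ~0.4 = Post40,
1 = Post100), optional per-subject kappa jitter (the uneven-enhancement
regime of real low-dose scans), a smooth fixed parenchymal texture shared
across dose levels, and additive Gaussian HU noise. Misalignment between
acquisitions — the respiratory/postural surrogate — is a smooth per-slice
random displacement field applied to a volume after generation, returned
alongside so registration recovery is measurable. Everything is
deterministic under the supplied seeds.

The phantom claims statistical structure, not anatomical realism: values
land in plausible abdominal soft-tissue HU ranges, vessels enhance most,
muscle not at all, and geometry drifts slowly along z.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .ctio import CTVolume, write_volume
from .roi import REFERENCE_REGION, RoiSet, mask_to_polygons, rasterize_polygons

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "BASELINE_HU",
    "ENHANCEMENT_HU",
    "generate_phantom_subject",
    "apply_misalignment",
    "warp_slice",
    "phantom_roi_set",
    "transport_points",
    "save_subject",
]

# Fixed attenuation tables (HU). Baselines sit in normal abdominal ranges;
# enhancement at kappa=1 is largest in vessels, moderate in parenchyma and
# zero in the epaxial-muscle reference and outside the body.
BASELINE_HU = {
    "background": -1000.0,
    "body": 30.0,
    "epaxial_muscle": 55.0,
    "liver": 60.0,
    "spleen": 50.0,
    "kidney_cortex": 35.0,
    "aorta": 45.0,
    "cvc": 42.0,
    "hepatic_vein": 48.0,
    "portal_vein": 46.0,
}
ENHANCEMENT_HU = {
    "background": 0.0,
    "body": 10.0,
    "epaxial_muscle": 0.0,
    "liver": 60.0,
    "spleen": 80.0,
    "kidney_cortex": 120.0,
    "aorta": 300.0,
    "cvc": 250.0,
    "hepatic_vein": 200.0,
    "portal_vein": 220.0,
}

# Organs get a smooth frozen texture (same across dose levels); vessels and
# background stay clean so region means follow the dose law exactly.
_TEXTURED = ("body", "epaxial_muscle", "liver", "spleen", "kidney_cortex")
_TEXTURE_SD_HU = 6.0
_TEXTURE_SMOOTH_PX = 8.0

# mask priority: later entries overwrite earlier ones where they overlap
_PAINT_ORDER = (
    "body", "liver", "spleen", "kidney_cortex", "epaxial_muscle",
    "aorta", "cvc", "hepatic_vein", "portal_vein",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    grid_size: pixels per axis of each (square) axial slice
    n_slices: axial slice count
    organ_layout_seed: seeds the anatomy (same seed => same anatomy)
    dose_fraction: default kappa when a single volume is requested
    noise_sd: additive Gaussian noise, HU
    deform_amplitude: maximum misalignment displacement, mm
    deform_smoothness: Gaussian scale of the random displacement field, mm
    n_landmarks: evaluation landmarks scattered inside the body
    pixel_spacing: in-plane spacing, mm; slice_spacing: z spacing, mm
    kappa_jitter: half-width of seeded per-subject dose-fraction jitter
    """

    grid_size: int = 256
    n_slices: int = 8
    organ_layout_seed: int = 0
    dose_fraction: float = 1.0
    noise_sd: float = 8.0
    deform_amplitude: float = 4.0
    deform_smoothness: float = 20.0
    n_landmarks: int = 24
    pixel_spacing: float = 1.0
    slice_spacing: float = 2.0
    kappa_jitter: float = 0.1

    def validate(self):
        if not (0.0 <= self.dose_fraction <= 1.0):
            raise ValueError(f"dose_fraction must be in [0,1], got {self.dose_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.deform_amplitude < 0:
            raise ValueError(f"deform_amplitude must be >= 0, got {self.deform_amplitude}")
        if self.grid_size < 32:
            raise ValueError(f"grid_size must be >= 32, got {self.grid_size}")
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom subject."""

    region_masks: dict[str, np.ndarray]          # name -> (nz, H, W) bool
    landmark_coords: np.ndarray                  # (K, 3) of (z, row, col) in mm
    true_fields: np.ndarray | None = None        # (nz, H, W, 2) px, pull-back warp
    kappas: dict[str, float] = field(default_factory=dict)  # dose tag -> jittered kappa


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _ellipse(H, W, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    y, x = yy - cy * H, xx - cx * W
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / (rx * W)) ** 2 + (v / (ry * H)) ** 2 <= 1.0


def _layout_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Paint the per-region masks for every slice, drifting slowly along z."""
    H = W = spec.grid_size
    rng = np.random.default_rng(spec.organ_layout_seed)
    jit = lambda s: rng.normal(0.0, s)
    # subject-level anatomy jitter
    base = {
        "body": (0.52 + jit(0.01), 0.50 + jit(0.01), 0.40, 0.45, 0.0),
        "liver": (0.42 + jit(0.02), 0.34 + jit(0.02), 0.20, 0.17, 0.4 + jit(0.1)),
        "spleen": (0.44 + jit(0.02), 0.76 + jit(0.02), 0.11, 0.07, -0.5),
        "kidney_cortex": (0.66 + jit(0.01), 0.68 + jit(0.02), 0.07, 0.05, 0.3),
        "epaxial_muscle": None,  # painted specially (two blobs)
        "aorta": (0.74 + jit(0.01), 0.54 + jit(0.01), 0.035, 0.035, 0.0),
        "cvc": (0.72 + jit(0.01), 0.43 + jit(0.01), 0.030, 0.040, 0.0),
        "hepatic_vein": (0.37 + jit(0.01), 0.37 + jit(0.01), 0.027, 0.027, 0.0),
        "portal_vein": (0.52 + jit(0.01), 0.42 + jit(0.01), 0.030, 0.030, 0.0),
    }
    drift_phase = rng.uniform(0, 2 * np.pi, size=len(_PAINT_ORDER))
    masks = {name: np.zeros((spec.n_slices, H, W), dtype=bool)
             for name in (*_PAINT_ORDER, "background")}
    for k in range(spec.n_slices):
        t = k / max(spec.n_slices - 1, 1)
        label = np.zeros((H, W), dtype=np.int16)  # 0 = background
        for idx, name in enumerate(_PAINT_ORDER):
            dz = 0.012 * np.sin(2 * np.pi * t + drift_phase[idx])
            scale = 1.0 + 0.08 * np.sin(np.pi * t + drift_phase[idx])
            if name == "epaxial_muscle":
                m = _ellipse(H, W, 0.86 + dz, 0.40, 0.055 * scale, 0.055)
                m |= _ellipse(H, W, 0.86 + dz, 0.60, 0.055 * scale, 0.055)
            else:
                cy, cx, ry, rx, ang = base[name]
                m = _ellipse(H, W, cy + dz, cx + dz * 0.5, ry * scale, rx * scale, ang)
            if name != "body":
                m &= label >= 1  # structures must lie inside the body
                label[m] = idx + 1
            else:
                label[m] = 1
        for idx, name in enumerate(_PAINT_ORDER):
            masks[name][k] = label == idx + 1
        masks["background"][k] = label == 0
        masks["body"][k] = label >= 1  # body superset of organs
    return masks


def _region_maps(spec: PhantomSpec, masks: dict[str, np.ndarray]):
    """Baseline / enhancement / texture HU maps from the region masks."""
    shape = masks["body"].shape
    baseline = np.full(shape, BASELINE_HU["background"], dtype=np.float64)
    enhance = np.zeros(shape, dtype=np.float64)
    exclusive = {n: m.copy() for n, m in masks.items() if n not in ("body", "background")}
    body_only = masks["body"].copy()
    for m in exclusive.values():
        body_only &= ~m
    paint = {"body": body_only, **exclusive}
    for name, m in paint.items():
        baseline[m] = BASELINE_HU[name]
        enhance[m] = ENHANCEMENT_HU[name]
    rng = np.random.default_rng(spec.organ_layout_seed + 7919)
    tex = gaussian_filter(rng.standard_normal(shape), (0, _TEXTURE_SMOOTH_PX, _TEXTURE_SMOOTH_PX))
    tex *= _TEXTURE_SD_HU / max(tex.std(), 1e-9)
    tex_mask = np.zeros(shape, dtype=bool)
    for name in _TEXTURED:
        tex_mask |= paint[name]
    baseline += np.where(tex_mask, tex, 0.0)
    return baseline, enhance


def generate_phantom_subject(
    spec: PhantomSpec,
    dose_levels: list[float] | None = None,
    seed: int = 0,
    dose_tags: list[str] | None = None,
    jitter_kappa: bool = False,
) -> tuple[list[CTVolume], PhantomTruth]:
    """Generate co-registered-in-truth phantom volumes at several dose levels.

    Returns one HU-domain :class:`CTVolume` per requested dose fraction plus
    the :class:`PhantomTruth` (masks, landmarks in mm). All volumes share
    the same anatomy; only the contrast enhancement and the noise draw
    differ. With ``jitter_kappa`` each subject perturbs its dose fractions
    by a seeded uniform offset (clipped to [0, 1]).
    """
    spec.validate()
    if dose_levels is None:
        dose_levels = [spec.dose_fraction]
    if not dose_levels:
        raise ValueError("dose_levels must be nonempty")
    for k in dose_levels:
        if not (0.0 <= k <= 1.0):
            raise ValueError(f"dose_fraction must be in [0,1], got {k}")
    if dose_tags is None:
        dose_tags = [f"dose{k:g}" for k in dose_levels]

    masks = _layout_masks(spec)
    baseline, enhance = _region_maps(spec, masks)
    rng = np.random.default_rng(seed)
    kappas: dict[str, float] = {}
    volumes: list[CTVolume] = []
    for kappa, tag in zip(dose_levels, dose_tags):
        k_eff = kappa
        if jitter_kappa and kappa > 0:
            k_eff = float(np.clip(kappa + rng.uniform(-spec.kappa_jitter, spec.kappa_jitter),
                                  0.0, 1.0))
        kappas[tag] = k_eff
        vox = baseline + k_eff * enhance
        if spec.noise_sd > 0:
            vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape)
        volumes.append(CTVolume(
            vox, (spec.pixel_spacing, spec.pixel_spacing, spec.slice_spacing),
            intensity_domain="HU",
        ))

    # landmarks inside an eroded body mask, uniformly over slices
    lm_rng = np.random.default_rng(spec.organ_layout_seed + 104729)
    interior = masks["body"] & ~masks["background"]
    coords = np.argwhere(interior)  # (n, 3) of (z, row, col)
    # keep away from the body boundary so interpolation tolerances are clean
    from scipy.ndimage import binary_erosion
    eroded = np.stack([binary_erosion(interior[z], iterations=6)
                       for z in range(spec.n_slices)])
    coords = np.argwhere(eroded)
    take = lm_rng.choice(len(coords), size=min(spec.n_landmarks, len(coords)), replace=False)
    lm_px = coords[take].astype(float)
    lm_mm = lm_px * np.array([spec.slice_spacing, spec.pixel_spacing, spec.pixel_spacing])
    truth = PhantomTruth(region_masks=masks, landmark_coords=lm_mm, kappas=kappas)
    return volumes, truth


# ---------------------------------------------------------------------------
# misalignment
# ---------------------------------------------------------------------------

def _random_field(H, W, amplitude_px, smooth_px, rng) -> np.ndarray:
    """Smooth random (drow, dcol) field with max magnitude = amplitude_px."""
    if amplitude_px == 0:
        return np.zeros((H, W, 2))
    raw = rng.standard_normal((2, H, W))
    sm = np.stack([gaussian_filter(r, smooth_px) for r in raw])
    mag = np.sqrt((sm ** 2).sum(axis=0)).max()
    if mag < 1e-12:
        return np.zeros((H, W, 2))
    return (sm * (amplitude_px / mag)).transpose(1, 2, 0)


def warp_slice(img: np.ndarray, field: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample through a pull-back field: out(x) = img(x + field(x))."""
    H, W = img.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    return map_coordinates(img.astype(np.float64),
                           [rr + field[..., 0], cc + field[..., 1]],
                           order=order, mode="nearest")


def _jacobian_folds(field: np.ndarray) -> float:
    """Fraction of pixels where det(I + grad d) <= 0 (folding)."""
    dyy, dyx = np.gradient(field[..., 0])
    dxy, dxx = np.gradient(field[..., 1])
    det = (1.0 + dyy) * (1.0 + dxx) - dyx * dxy
    return float((det <= 0).mean())


def apply_misalignment(volume: CTVolume, spec: PhantomSpec,
                       seed: int = 0) -> tuple[CTVolume, np.ndarray]:
    """Apply a smooth per-slice random misalignment to a volume.

    Returns the warped volume and the applied fields, shape
    ``(n_slices, H, W, 2)`` in pixels with pull-back convention
    ``warped(x) = volume(x + field(x))``. Raises if the requested
    amplitude folds the grid (any Jacobian determinant <= 0).
    """
    spec.validate()
    nz, H, W = volume.voxels.shape
    amp_px = spec.deform_amplitude / spec.pixel_spacing
    smooth_px = spec.deform_smoothness / spec.pixel_spacing
    rng = np.random.default_rng(seed)
    fields = np.zeros((nz, H, W, 2))
    out = np.empty_like(volume.voxels, dtype=np.float64)
    for z in range(nz):
        f = _random_field(H, W, amp_px, smooth_px, rng)
        folds = _jacobian_folds(f)
        if folds > 0:
            raise ValueError(
                f"deform_amplitude {spec.deform_amplitude} mm folds the grid "
                f"on slice {z} ({folds:.1%} of pixels with non-positive Jacobian)"
            )
        fields[z] = f
        out[z] = warp_slice(volume.voxels[z], f) if amp_px > 0 else volume.voxels[z]
    from dataclasses import replace
    return replace(volume, voxels=out), fields


def transport_points(field: np.ndarray, points: np.ndarray,
                     n_iter: int = 30) -> np.ndarray:
    """Where does each point of the un-warped image land in the warped image?

    For the pull-back convention ``warped(x) = img(x + d(x))`` the warped
    location ``x*`` of a source point ``q`` solves ``x* + d(x*) = q``;
    solved by fixed-point iteration (converges for smooth sub-unit-Jacobian
    fields).
    """
    pts = np.asarray(points, dtype=float)
    x = pts.copy()
    for _ in range(n_iter):
        d = np.stack([
            map_coordinates(field[..., 0], [x[:, 0], x[:, 1]], order=1, mode="nearest"),
            map_coordinates(field[..., 1], [x[:, 0], x[:, 1]], order=1, mode="nearest"),
        ], axis=1)
        x = pts - d
    return x


# ---------------------------------------------------------------------------
# ROI extraction & export
# ---------------------------------------------------------------------------

def phantom_roi_set(truth: PhantomTruth, slice_index: int,
                    min_pixels: int = 8) -> RoiSet:
    """Trace each nonempty region mask of one slice into boundary polygons."""
    roi = RoiSet(source_image_tag=f"slice_{slice_index:04d}")
    any_region = False
    for name, masks in truth.region_masks.items():
        if name in ("body", "background"):
            continue
        mask = masks[slice_index]
        if mask.sum() < min_pixels:
            continue
        polys = mask_to_polygons(mask)
        if not polys:
            continue
        for p in polys:
            roi.add(name, p)
        any_region = True
        # rasterization fidelity guard (IoU vs the source mask)
        rast = rasterize_polygons(roi.regions[name], mask.shape)
        iou = (rast & mask).sum() / max((rast | mask).sum(), 1)
        if iou < 0.95:
            roi.flags.append(f"region {name!r} polygon IoU {iou:.3f} < 0.95")
    if not any_region:
        roi.flags.append("empty slice: no nonempty region masks")
    return roi


def save_subject(out_dir: str, subject_id: str, volumes: dict[str, CTVolume],
                 truth: PhantomTruth):
    """Write a phantom subject: NIfTI volumes + masks, landmark CSV, ROI JSON."""
    sdir = os.path.join(out_dir, subject_id)
    os.makedirs(sdir, exist_ok=True)
    for tag, vol in volumes.items():
        write_volume(vol, os.path.join(sdir, f"{tag}.nii.gz"))
    for name, mask in truth.region_masks.items():
        mv = CTVolume(mask.astype(np.uint8) * 255,
                      spacing=next(iter(volumes.values())).spacing,
                      intensity_domain="uint8")
        write_volume(mv, os.path.join(sdir, f"mask_{name}.nii.gz"))
    pd.DataFrame(truth.landmark_coords, columns=["z_mm", "row_mm", "col_mm"]).to_csv(
        os.path.join(sdir, "landmarks.csv"), index=False)
    from .ctio import write_roi_polygons
    n_slices = truth.region_masks["body"].shape[0]
    for z in range(n_slices):
        roi = phantom_roi_set(truth, z)
        if not roi.empty:
            write_roi_polygons(roi, os.path.join(sdir, f"roi_{z:04d}.json"))
    return sdir
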