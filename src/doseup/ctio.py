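"""CT volume I/O and the slice-level preprocessing chain.

The pipeline standardizes heterogeneous CT acquisitions into the form the
translation network trains on: Hounsfield-unit volumes are soft-tissue
windowed (center 40 HU, width 400 HU) and mapped to [0, 1], resampled to a
common voxel spacing (0.5 x 0.5 x 2.0 mm, linear interpolation), each axial
slice is center-cropped / zero-padded to 512 x 512 and bilinearly resized to
the training size (256 x 256 by default), and slices from different
acquisitions of the same subject are paired by nearest absolute physical
z-coordinate. For metric evaluation, unit-domain images are quantized to
8-bit with round-half-away-from-zero.

Conventions (the tie-break and centering rules matter for reproducibility):

* voxel arrays are indexed ``[z, row, col]``; world z of slice ``k`` is
  ``origin_z + k * dz`` after orientation standardization;
* crop/pad is centered geometrically; odd remainders go to the
  bottom/right;
* slice pairing is fixed-driven: every fixed slice whose nearest moving
  slice lies within half a slice spacing of it (the moving z-range
  extended by dz/2 at both ends) gets that nearest moving slice, ties
  broken toward the lower z; one moving slice may serve several fixed
  slices.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .roi import RoiSet, labelme_to_roiset, roiset_to_labelme

__all__ = [
    "CTVolume",
    "SlicePair",
    "read_volume",
    "write_volume",
    "window_normalize",
    "resample",
    "standardize_plane",
    "pair_slices",
    "to_eval_uint8",
    "from_eval_uint8",
    "read_roi_polygons",
    "write_roi_polygons",
    "write_png",
    "read_png",
]

INTENSITY_DOMAINS = ("HU", "unit", "uint8")
DEFAULT_WINDOW_CENTER = 40.0
DEFAULT_WINDOW_WIDTH = 400.0
DEFAULT_TARGET_SPACING = (0.5, 0.5, 2.0)
CANVAS_SIZE = 512
DEFAULT_TRAIN_SIZE = 256


@dataclass
class CTVolume:
    """Oriented voxel grid with spacing, origin and intensity-domain flag."""

    voxels: np.ndarray                       # (nz, ny, nx)
    spacing: tuple[float, float, float]      # (dx, dy, dz) in mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    intensity_domain: str = "HU"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal (tol 1e-6)")
        if self.intensity_domain not in INTENSITY_DOMAINS:
            raise ValueError(f"intensity_domain must be one of {INTENSITY_DOMAINS}")
        if self.intensity_domain == "unit":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"unit-domain volume has values outside [0,1]: [{lo},{hi}]")
        if self.intensity_domain == "uint8":
            if self.voxels.dtype != np.uint8:
                raise ValueError("uint8-domain volume must have dtype uint8")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def z_coords(self) -> np.ndarray:
        """Physical z-coordinate (mm) of each axial slice."""
        return self.origin[2] + np.arange(self.n_slices) * self.spacing[2]


@dataclass
class SlicePair:
    """A z-matched fixed/moving slice pair from two acquisitions."""

    fixed_slice: np.ndarray
    moving_slice: np.ndarray
    fixed_z: float
    moving_z: float
    subject_id: str
    fixed_domain: str
    moving_domain: str
    fixed_index: int
    moving_index: int

    @property
    def pairing_distance(self) -> float:
        return abs(self.fixed_z - self.moving_z)


# ---------------------------------------------------------------------------
# reading / writing volumes
# ---------------------------------------------------------------------------

def read_volume(path: str) -> CTVolume:
    """Read a NIfTI-1 file or a DICOM series directory into HU voxels."""
    if os.path.isdir(path):
        return _read_dicom_series(path)
    return _read_nifti(path)


def _read_nifti(path: str) -> CTVolume:
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)  # (x, y, z)
    voxels = np.transpose(data, (2, 1, 0))
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    rot = img.affine[:3, :3] / np.array([dx, dy, dz])
    return CTVolume(voxels, (dx, dy, dz), origin, rot, intensity_domain="HU")


def _read_dicom_series(path: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(f) for f in files]
    orients = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 6)) for s in slices}
    if len(orients) > 1:
        raise ValueError(f"mixed-orientation DICOM series: found orientations {sorted(orients)}")
    for s in slices:
        if "RescaleSlope" not in s or "RescaleIntercept" not in s:
            raise ValueError(
                "missing rescale tags RescaleSlope (0028,1053) / RescaleIntercept (0028,1052)"
            )
    row_dir, col_dir = np.asarray(slices[0].ImageOrientationPatient, float).reshape(2, 3)
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    vox = np.stack(
        [s.pixel_array * float(s.RescaleSlope) + float(s.RescaleIntercept) for s in slices]
    ).astype(np.float64)
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        z0 = float(np.dot(np.asarray(slices[0].ImagePositionPatient, float), normal))
        z1 = float(np.dot(np.asarray(slices[1].ImagePositionPatient, float), normal))
        dz = abs(z1 - z0)
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    direction = np.stack([row_dir, col_dir, normal])
    return CTVolume(vox, (dx, dy, dz), origin, direction, intensity_domain="HU")


def write_volume(volume: CTVolume, path: str):
    """Write a CTVolume as NIfTI-1 (float for HU/unit, uint8 for uint8)."""
    data = np.transpose(volume.voxels, (2, 1, 0))
    dx, dy, dz = volume.spacing
    affine = np.eye(4)
    affine[:3, :3] = volume.direction * np.array([dx, dy, dz])
    affine[:3, 3] = volume.origin
    dtype = np.uint8 if volume.intensity_domain == "uint8" else np.float32
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, path)


# ---------------------------------------------------------------------------
# intensity & geometry standardization
# ---------------------------------------------------------------------------

def window_normalize(volume: CTVolume, center: float = DEFAULT_WINDOW_CENTER,
                     width: float = DEFAULT_WINDOW_WIDTH) -> CTVolume:
    """Clip HU to the window and map affinely to [0, 1]."""
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    if volume.intensity_domain != "HU":
        raise ValueError(f"window_normalize expects HU input, got {volume.intensity_domain}")
    lo, hi = center - width / 2.0, center + width / 2.0
    vox = (np.clip(volume.voxels, lo, hi) - lo) / width
    return replace(volume, voxels=vox, intensity_domain="unit")


def resample(volume: CTVolume,
             target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING) -> CTVolume:
    """Linearly resample onto an axis-aligned grid with the target spacing.

    The output grid starts at the input origin and covers the input physical
    extent; output sample ``i`` along an axis sits at physical offset
    ``i * target``, i.e. input index coordinate ``i * target / source``.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    src = volume.spacing
    shape = volume.voxels.shape  # (nz, ny, nx)
    src_zyx = (src[2], src[1], src[0])
    tgt_zyx = (target_spacing[2], target_spacing[1], target_spacing[0])
    new_shape = tuple(
        int(np.floor((n - 1) * s / t + 1e-9)) + 1
        for n, s, t in zip(shape, src_zyx, tgt_zyx)
    )
    axes = [np.arange(n) * t / s for n, s, t in zip(new_shape, src_zyx, tgt_zyx)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    vox = map_coordinates(volume.voxels.astype(np.float64), [zz, yy, xx],
                          order=1, mode="nearest")
    if volume.intensity_domain == "unit":
        vox = np.clip(vox, 0.0, 1.0)
    return replace(volume, voxels=vox, spacing=tuple(target_spacing))


def _center_crop_pad(img: np.ndarray, size: int) -> np.ndarray:
    """Center crop or zero-pad to ``size`` x ``size``; odd remainder bottom/right."""
    out = img
    for axis in (0, 1):
        n = out.shape[axis]
        if n > size:
            start = (n - size) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + size)
            out = out[tuple(sl)]
        elif n < size:
            before = (size - n) // 2
            after = size - n - before
            width = [(0, 0), (0, 0)]
            width[axis] = (before, after)
            out = np.pad(out, width, mode="constant")
    return out


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize with corner-aligned sampling (exact for constants)."""
    h, w = img.shape
    rows = np.linspace(0, h - 1, size)
    cols = np.linspace(0, w - 1, size)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(img.astype(np.float64), [rr, cc], order=1, mode="nearest")


def standardize_plane(slice2d: np.ndarray, train_size: int = DEFAULT_TRAIN_SIZE,
                      canvas: int = CANVAS_SIZE) -> np.ndarray:
    """Center crop/zero-pad to the 512-canvas, then bilinear-resize for training."""
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("standardize_plane expects a 2-D slice")
    img = _center_crop_pad(img, canvas)
    if train_size != canvas:
        img = _bilinear_resize(img, train_size)
    return np.clip(img, 0.0, 1.0)


def pair_slices(fixed: CTVolume, moving: CTVolume, subject_id: str = "",
                fixed_domain: str = "fixed", moving_domain: str = "moving") -> list[SlicePair]:
    """Pair each in-range fixed slice with its nearest moving slice by |dz|.

    A fixed slice is in range when it lies within the moving z-range
    extended by half the moving slice spacing on either end — i.e. when
    its nearest moving slice is at most dz/2 away; surplus cranial/caudal
    slices beyond that lack a corresponding partner and are excluded.
    Equidistant candidates resolve to the lower z. Returns pairs sorted
    by fixed z.
    """
    fz, mz = fixed.z_coords, moving.z_coords
    half = moving.spacing[2] / 2.0
    lo, hi = float(mz.min()) - half, float(mz.max()) + half
    pairs: list[SlicePair] = []
    for i, z in enumerate(fz):
        if z < lo or z > hi:
            continue
        d = np.abs(mz - z)
        best = int(np.flatnonzero(d == d.min())[0])  # ties -> lower z (sorted grid)
        pairs.append(SlicePair(
            fixed_slice=fixed.voxels[i], moving_slice=moving.voxels[best],
            fixed_z=float(z), moving_z=float(mz[best]), subject_id=subject_id,
            fixed_domain=fixed_domain, moving_domain=moving_domain,
            fixed_index=i, moving_index=best,
        ))
    if not pairs:
        warnings.warn("pair_slices: no z-overlap between volumes; returning empty list")
    pairs.sort(key=lambda p: p.fixed_z)
    return pairs


# ---------------------------------------------------------------------------
# 8-bit evaluation convention
# ---------------------------------------------------------------------------

def to_eval_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a unit-domain image to uint8: round(v*255), half away from zero."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError(
            f"to_eval_uint8 expects values in [0,1]; got [{arr.min():.4g},{arr.max():.4g}]"
        )
    q = np.floor(arr * 255.0 + 0.5)  # half-away-from-zero == half-up for v >= 0
    return np.clip(q, 0, 255).astype(np.uint8)


def from_eval_uint8(image: np.ndarray) -> np.ndarray:
    """Map uint8 back to the unit domain (v / 255)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("from_eval_uint8 expects a uint8 image")
    return arr.astype(np.float64) / 255.0


def write_png(image: np.ndarray, path: str):
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("write_png expects a uint8 image; quantize with to_eval_uint8")
    Image.fromarray(arr, mode="L").save(path)


def read_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# ROI annotations (LabelMe-dialect JSON)
# ---------------------------------------------------------------------------

def read_roi_polygons(path: str) -> RoiSet:
    with open(path) as fh:
        doc = json.load(fh)
    return labelme_to_roiset(doc, source=os.path.basename(path))


def write_roi_polygons(roi: RoiSet, path: str, image_shape: tuple[int, int] | None = None):
    doc = roiset_to_labelme(roi, image_shape=image_shape)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
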