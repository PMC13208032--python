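"""Region-of-interest polygons: the shared vocabulary, rasterization and
LabelMe-dialect JSON round-trip.

Polygons are stored as LabelMe does: ``(x, y)`` vertex lists in pixel
coordinates, where ``x`` is the column and ``y`` the row. Rasterization
uses a center-of-pixel inclusion rule — pixel ``(r, c)`` belongs to a
polygon iff the point ``(c, r)`` lies inside it or on its boundary — so a
square polygon whose corners sit on pixel centers contains exactly the
pixels whose centers it spans.

The region vocabulary mirrors the seven anatomical regions evaluated for
contrast-to-noise ratio (aorta, caudal vena cava, hepatic vein, portal
vein, spleen, liver, kidney cortex) plus the epaxial muscle, which serves
as the non-enhancing reference tissue. Unknown labels are preserved and
flagged rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure

__all__ = [
    "RoiSet",
    "CNR_REGIONS",
    "REFERENCE_REGION",
    "canonical_label",
    "rasterize_polygons",
    "mask_to_polygons",
    "labelme_to_roiset",
    "roiset_to_labelme",
]

CNR_REGIONS = (
    "aorta",
    "cvc",
    "hepatic_vein",
    "portal_vein",
    "spleen",
    "liver",
    "kidney_cortex",
)
REFERENCE_REGION = "epaxial_muscle"

_LABEL_SYNONYMS = {
    "aorta": "aorta",
    "cvc": "cvc",
    "caudal vena cava": "cvc",
    "caudal_vena_cava": "cvc",
    "hepatic vein": "hepatic_vein",
    "hepatic_vein": "hepatic_vein",
    "hv": "hepatic_vein",
    "portal vein": "portal_vein",
    "portal_vein": "portal_vein",
    "pv": "portal_vein",
    "spleen": "spleen",
    "liver": "liver",
    "kidney cortex": "kidney_cortex",
    "kidney_cortex": "kidney_cortex",
    "kidney": "kidney_cortex",
    "epaxial muscle": "epaxial_muscle",
    "epaxial_muscle": "epaxial_muscle",
    "muscle": "epaxial_muscle",
}


def canonical_label(label: str) -> tuple[str, bool]:
    """Map a free-text annotation label to the region vocabulary.

    Returns ``(canonical_name, known)``; unknown labels come back
    normalized (lower-case, underscores) with ``known=False``.
    """
    key = label.strip().lower().replace("-", " ")
    if key in _LABEL_SYNONYMS:
        return _LABEL_SYNONYMS[key], True
    return key.replace(" ", "_"), False


@dataclass
class RoiSet:
    """Polygons grouped per anatomical region for one slice."""

    regions: dict[str, list[np.ndarray]] = field(default_factory=dict)  # name -> [(V,2) xy]
    source_image_tag: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def reference_polygons(self) -> list[np.ndarray]:
        return self.regions.get(REFERENCE_REGION, [])

    @property
    def empty(self) -> bool:
        return not any(len(p) for p in self.regions.values())

    def add(self, name: str, polygon: np.ndarray):
        poly = np.asarray(polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError(f"polygon for {name!r} must be (V>=3, 2) xy vertices")
        self.regions.setdefault(name, []).append(poly)

    def region_mask(self, name: str, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize all polygons of a region, pooled into one boolean mask."""
        return rasterize_polygons(self.regions.get(name, []), shape)


def rasterize_polygons(polygons: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Center-of-pixel rasterization (boundary-inclusive) of xy polygons.

    Multiple polygons combine under the even-odd rule: a pixel belongs to
    the region iff its center lies in an odd number of polygons. For the
    usual disjoint multi-ROI annotations this is plain union; a polygon
    nested inside another (a traced hole, e.g. a vessel running through an
    organ) is carved out.
    """
    count = np.zeros(shape, dtype=np.int32)
    if not polygons:
        return count.astype(bool)
    H, W = shape
    cc, rr = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    for poly in polygons:
        sp = ShapelyPolygon(np.asarray(poly, dtype=float))
        if not sp.is_valid:
            sp = sp.buffer(0)
        if sp.is_empty:
            continue
        minx, miny, maxx, maxy = sp.bounds
        c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, W)
        r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, H)
        if c0 >= c1 or r0 >= r1:
            continue
        sub_c = cc[r0:r1, c0:c1].ravel()
        sub_r = rr[r0:r1, c0:c1].ravel()
        inside = shapely.intersects_xy(sp, sub_c, sub_r)
        count[r0:r1, c0:c1] += inside.reshape(r1 - r0, c1 - c0)
    return (count % 2) == 1


def mask_to_polygons(mask: np.ndarray, tolerance: float = 0.3) -> list[np.ndarray]:
    """Trace the boundary of a binary mask into simplified xy polygons.

    Marching squares at level 0.5 on a zero-padded copy, so regions touching
    the image border close properly; contours are simplified with a small
    tolerance and returned as (V, 2) ``(x, y)`` arrays.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        contour = measure.approximate_polygon(contour, tolerance) - 1.0  # un-pad
        if len(contour) < 4:  # closed contour repeats first vertex
            continue
        xy = contour[:-1][:, ::-1]  # (row, col) -> (x, y), drop duplicate end
        if len(xy) >= 3:
            polys.append(xy)
    return polys


# ---------------------------------------------------------------------------
# LabelMe-dialect JSON
# ---------------------------------------------------------------------------

def labelme_to_roiset(doc: dict, source: str = "") -> RoiSet:
    roi = RoiSet(source_image_tag=doc.get("imagePath", source))
    for shape in doc.get("shapes", []):
        label = shape.get("label", "")
        points = np.asarray(shape.get("points", []), dtype=float)
        if points.ndim != 2 or len(points) < 3:
            msg = f"skipped shape {label!r}: needs >= 3 vertices, got {len(points)}"
            roi.flags.append(msg)
            warnings.warn(msg)
            continue
        name, known = canonical_label(label)
        if not known:
            roi.flags.append(f"unknown label {label!r} kept as {name!r}")
        roi.add(name, points)
    return roi


def roiset_to_labelme(roi: RoiSet, image_shape: tuple[int, int] | None = None) -> dict:
    shapes = []
    for name, polys in roi.regions.items():
        for poly in polys:
            shapes.append({
                "label": name,
                "points": [[float(x), float(y)] for x, y in poly],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            })
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": roi.source_image_tag,
        "imageData": None,
    }
    if image_shape is not None:
        doc["imageHeight"], doc["imageWidth"] = int(image_shape[0]), int(image_shape[1])
    return doc
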