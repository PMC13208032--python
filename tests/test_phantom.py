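"""Phantom generator: dose law, determinism, misalignment, ROI tracing."""

import numpy as np
import pytest

from doseup.phantom import (BASELINE_HU, ENHANCEMENT_HU, PhantomSpec,
                            apply_misalignment, generate_phantom_subject,
                            phantom_roi_set, transport_points, warp_slice)
from doseup.roi import rasterize_polygons


@pytest.fixture(scope="module")
def clean_subject():
    spec = PhantomSpec(grid_size=128, n_slices=4, organ_layout_seed=3, noise_sd=0.0)
    vols, truth = generate_phantom_subject(spec, [0.0, 0.4, 1.0], seed=1)
    return spec, vols, truth


def test_zero_dose_identity_and_enhancement_map(clean_subject):
    """kappa=0 vs kappa=1 differ exactly by the enhancement map; the
    epaxial-muscle reference and the background never enhance."""
    spec, (pre, p40, p100), truth = clean_subject
    diff = p100.voxels - pre.voxels
    for region in ("epaxial_muscle", "background"):
        assert np.abs(diff[truth.region_masks[region]]).max() == 0.0
    assert np.abs(diff[truth.region_masks["aorta"]]
                  - ENHANCEMENT_HU["aorta"]).max() < 1e-9


@pytest.mark.parametrize("region", ["aorta", "cvc", "hepatic_vein", "portal_vein"])
def test_vessel_mean_follows_dose_law(clean_subject, region):
    """Mask-averaged vessel intensity equals baseline + kappa*enhancement."""
    spec, (pre, p40, p100), truth = clean_subject
    mask = truth.region_masks[region]
    expected = BASELINE_HU[region] + 0.4 * ENHANCEMENT_HU[region]
    assert p40.voxels[mask].mean() == pytest.approx(expected, abs=1e-9)


def test_dose_monotonicity_and_determinism():
    spec = PhantomSpec(grid_size=96, n_slices=2, organ_layout_seed=5, noise_sd=0.0)
    kappas = [0.0, 0.25, 0.5, 0.75, 1.0]
    vols, truth = generate_phantom_subject(spec, kappas, seed=9)
    for region in ("aorta", "liver", "spleen", "kidney_cortex"):
        means = [v.voxels[truth.region_masks[region]].mean() for v in vols]
        assert all(b >= a for a, b in zip(means, means[1:]))
    for region in ("epaxial_muscle", "background"):
        means = [v.voxels[truth.region_masks[region]].mean() for v in vols]
        assert np.ptp(means) < 1e-9
    vols2, _ = generate_phantom_subject(spec, kappas, seed=9)
    for a, b in zip(vols, vols2):
        assert (a.voxels == b.voxels).all()


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match="dose_fraction"):
        PhantomSpec(dose_fraction=1.5).validate()
    with pytest.raises(ValueError, match="noise_sd"):
        PhantomSpec(noise_sd=-1.0).validate()
    spec = PhantomSpec()
    with pytest.raises(ValueError, match="dose_fraction"):
        generate_phantom_subject(spec, [2.0], seed=0)


def test_identity_warp_at_zero_amplitude(clean_subject):
    spec, vols, _ = clean_subject
    spec0 = PhantomSpec(**{**spec.__dict__, "deform_amplitude": 0.0})
    warped, fields = apply_misalignment(vols[2], spec0, seed=4)
    assert (warped.voxels == vols[2].voxels).all()
    assert np.abs(fields).max() == 0.0


def test_misalignment_field_bounded_and_smooth(clean_subject):
    spec, vols, truth = clean_subject
    warped, fields = apply_misalignment(vols[2], spec, seed=4)
    mag = np.sqrt((fields ** 2).sum(-1))
    assert mag.max() <= spec.deform_amplitude / spec.pixel_spacing + 1e-9
    # near-volume-preserving: warped body area within 5% of the original
    body = truth.region_masks["body"][1].astype(float)
    warped_body = warp_slice(body, fields[1]) > 0.5
    assert abs(warped_body.sum() - body.sum()) / body.sum() < 0.05


def test_known_field_displaces_delta_spot():
    """A delta spot warped through a constant field moves by exactly the
    field value (centroid oracle, interpolation tolerance)."""
    img = np.zeros((64, 64))
    img[30:33, 40:43] = 1.0
    field = np.zeros((64, 64, 2))
    field[..., 0] = 2.5   # out(x) = img(x + d) -> content moves by -d
    field[..., 1] = -1.5
    warped = warp_slice(img, field)
    rr, cc = np.mgrid[0:64, 0:64]
    c0 = np.array([(img * rr).sum(), (img * cc).sum()]) / img.sum()
    c1 = np.array([(warped * rr).sum(), (warped * cc).sum()]) / warped.sum()
    assert np.abs((c1 - c0) - [-2.5, 1.5]).max() < 0.05


def test_landmark_transport_matches_warped_volume(clean_subject):
    """Transported landmarks land on the same anatomy in the warped image."""
    spec, vols, truth = clean_subject
    warped, fields = apply_misalignment(vols[2], spec, seed=8)
    z = 1
    lm = truth.landmark_coords[truth.landmark_coords[:, 0] == z * spec.slice_spacing]
    pts = lm[:, 1:] / spec.pixel_spacing
    moved = transport_points(fields[z], pts)
    # residual of the defining fixed-point equation below interpolation tol
    from scipy.ndimage import map_coordinates
    d = np.stack([map_coordinates(fields[z][..., k], [moved[:, 0], moved[:, 1]],
                                  order=1) for k in range(2)], 1)
    assert np.abs(moved + d - pts).max() < 0.5


def test_folding_amplitude_rejected():
    spec = PhantomSpec(grid_size=64, n_slices=1, deform_amplitude=40.0,
                       deform_smoothness=3.0)
    vols, _ = generate_phantom_subject(spec, [1.0], seed=0)
    with pytest.raises(ValueError, match="fold"):
        apply_misalignment(vols[0], spec, seed=1)


def test_roi_polygons_recover_masks(clean_subject):
    spec, vols, truth = clean_subject
    roi = phantom_roi_set(truth, 1)
    assert not roi.flags
    for name, polys in roi.regions.items():
        mask = truth.region_masks[name][1]
        rast = rasterize_polygons(polys, mask.shape)
        iou = (rast & mask).sum() / (rast | mask).sum()
        assert iou >= 0.95, name


def test_roi_square_and_empty_slice():
    import doseup.phantom as P
    truth = P.PhantomTruth(
        region_masks={"aorta": np.zeros((1, 20, 20), bool),
                      "body": np.zeros((1, 20, 20), bool),
                      "background": np.ones((1, 20, 20), bool)},
        landmark_coords=np.zeros((0, 3)))
    truth.region_masks["aorta"][0, 5:15, 5:15] = True
    roi = phantom_roi_set(truth, 0)
    rast = rasterize_polygons(roi.regions["aorta"], (20, 20))
    assert (rast == truth.region_masks["aorta"][0]).all()  # IoU exactly 1
    empty = P.PhantomTruth(
        region_masks={"aorta": np.zeros((1, 20, 20), bool),
                      "body": np.zeros((1, 20, 20), bool),
                      "background": np.ones((1, 20, 20), bool)},
        landmark_coords=np.zeros((0, 3)))
    roi2 = phantom_roi_set(empty, 0)
    assert roi2.empty and roi2.flags
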