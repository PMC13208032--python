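"""I/O and preprocessing: windowing, resampling, pairing, quantization."""

import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseup.ctio import (CTVolume, from_eval_uint8, pair_slices, read_volume,
                         resample, standardize_plane, to_eval_uint8,
                         window_normalize, write_volume)


def _vol(voxels, spacing=(1.0, 1.0, 2.0), **kw):
    return CTVolume(np.asarray(voxels, dtype=float), spacing, **kw)


# -- container invariants ----------------------------------------------------

def test_volume_invariants():
    with pytest.raises(ValueError, match="spacing"):
        _vol(np.zeros((2, 4, 4)), spacing=(0.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="orthonormal"):
        CTVolume(np.zeros((2, 4, 4)), (1, 1, 1), direction=np.ones((3, 3)))
    with pytest.raises(ValueError, match="unit"):
        CTVolume(np.full((1, 2, 2), 2.0), (1, 1, 1), intensity_domain="unit")


def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    vol = _vol(rng.normal(40, 100, (3, 16, 16)), spacing=(0.7, 0.7, 2.5))
    path = os.path.join(tmp_path, "v.nii.gz")
    write_volume(vol, path)
    back = read_volume(path)
    assert np.allclose(back.voxels, vol.voxels, atol=1e-4)
    assert back.spacing == pytest.approx(vol.spacing)


def test_dicom_rescale_and_orientation(tmp_path):
    pydicom = pytest.importorskip("pydicom")
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    def make_slice(path, z, orientation, stored):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows = ds.Columns = 4
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [1.0, 1.0]
        ds.ImageOrientationPatient = orientation
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = np.full((4, 4), stored, dtype=np.uint16).tobytes()
        ds.save_as(path, enforce_file_format=True)

    d = tmp_path / "series"
    d.mkdir()
    make_slice(str(d / "a.dcm"), 0, [1, 0, 0, 0, 1, 0], 1024)
    make_slice(str(d / "b.dcm"), 2, [1, 0, 0, 0, 1, 0], 1124)
    vol = read_volume(str(d))
    assert vol.voxels[0].max() == pytest.approx(0.0)    # 1024*1 - 1024
    assert vol.voxels[1].max() == pytest.approx(100.0)
    make_slice(str(d / "c.dcm"), 4, [0, 1, 0, 1, 0, 0], 1024)
    with pytest.raises(ValueError, match="mixed-orientation"):
        read_volume(str(d))


# -- windowing ---------------------------------------------------------------

@pytest.mark.parametrize("hu,expected", [(-160.0, 0.0), (240.0, 1.0),
                                         (40.0, 0.5), (140.0, 0.75),
                                         (-500.0, 0.0), (400.0, 1.0)])
def test_window_bounds(hu, expected):
    out = window_normalize(_vol(np.full((1, 2, 2), hu)))
    assert out.voxels.flat[0] == pytest.approx(expected)
    assert out.intensity_domain == "unit"


def test_window_monotone_and_requires_hu():
    vals = np.linspace(-300, 300, 50).reshape(1, 5, 10)
    out = window_normalize(_vol(vals)).voxels.ravel()
    assert (np.diff(out) >= -1e-12).all()
    with pytest.raises(ValueError, match="width"):
        window_normalize(_vol(vals), width=0)
    with pytest.raises(ValueError, match="HU"):
        window_normalize(window_normalize(_vol(vals)))


# -- resampling --------------------------------------------------------------

def test_resample_identity_and_constant():
    rng = np.random.default_rng(1)
    vol = _vol(rng.random((4, 8, 8)), spacing=(0.5, 0.5, 2.0))
    same = resample(vol, (0.5, 0.5, 2.0))
    assert np.allclose(same.voxels, vol.voxels, atol=1e-12)
    const = resample(_vol(np.full((3, 6, 6), 7.0), spacing=(1.0, 1.0, 4.0)))
    assert np.allclose(const.voxels, 7.0)
    with pytest.raises(ValueError, match="positive"):
        resample(vol, (0.5, 0.5, -1.0))


def test_resample_linear_ramp_midpoints():
    """Halving dz on a linear ramp puts midpoints at neighbour means."""
    nz = 5
    ramp = np.tile(np.arange(nz, dtype=float)[:, None, None], (1, 4, 4))
    vol = _vol(ramp, spacing=(1.0, 1.0, 4.0))
    out = resample(vol, (1.0, 1.0, 2.0))
    assert out.voxels.shape[0] == 2 * nz - 1
    for i in range(nz - 1):
        mid = out.voxels[2 * i + 1, 0, 0]
        assert mid == pytest.approx((ramp[i, 0, 0] + ramp[i + 1, 0, 0]) / 2)


# -- plane standardization ---------------------------------------------------

def test_standardize_crop_and_pad():
    big = np.zeros((600, 600))
    big[44:556, 44:556] = 1.0  # central 512x512 block
    out = standardize_plane(big, train_size=512)
    assert out.shape == (512, 512) and np.allclose(out, 1.0)
    tall = np.ones((300, 512))
    out = standardize_plane(tall, train_size=512)
    assert out.shape == (512, 512)
    assert np.allclose(out[106:406], 1.0)        # 212 pad split 106/106
    assert np.allclose(out[:106], 0.0) and np.allclose(out[406:], 0.0)


def test_standardize_constant_preserved():
    out = standardize_plane(np.full((512, 512), 0.37))
    assert out.shape == (256, 256)
    assert np.allclose(out, 0.37)


# -- z-coordinate slice pairing ----------------------------------------------

def _zvol(zs, dz, origin_z=0.0):
    # CTVolume z-grid is origin + k*dz; build from explicit start
    n = len(zs)
    return CTVolume(np.arange(n, dtype=float)[:, None, None] * np.ones((1, 2, 2)),
                    (1.0, 1.0, dz), origin=(0.0, 0.0, origin_z))


def test_pairing_example_and_exclusion():
    fixed = _zvol(range(4), 2.0)               # z = 0,2,4,6
    moving = _zvol(range(5), 2.0, origin_z=1)  # z = 1,3,5,7,9
    pairs = pair_slices(fixed, moving)
    assert len(pairs) == 4
    assert all(p.pairing_distance <= 1.0 for p in pairs)
    assert 4 not in {p.moving_index for p in pairs}  # moving z=9 unused
    # ties resolve to the lower z
    assert pairs[1].moving_z == 1.0  # fixed z=2 equidistant to 1 and 3


def test_pairing_identity_and_disjoint():
    fixed = _zvol(range(5), 2.0)
    pairs = pair_slices(fixed, fixed)
    assert [p.moving_index for p in pairs] == list(range(5))
    assert all(p.pairing_distance == 0.0 for p in pairs)
    far = _zvol(range(5), 2.0, origin_z=100.0)
    with pytest.warns(UserWarning, match="no z-overlap"):
        assert pair_slices(fixed, far) == []


def test_pairing_matches_bruteforce_on_random_grids():
    """Fixed-driven nearest-neighbour pairing equals exhaustive search
    (lower-z tie rule) on 1000 random z-grids."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        nf, nm = rng.integers(1, 12, size=2)
        fo, mo = rng.integers(-10, 10, size=2) * 2.0
        fixed = _zvol(range(nf), 2.0, origin_z=fo)
        moving = _zvol(range(nm), 2.0, origin_z=mo)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = pair_slices(fixed, moving)
        fz, mz = fixed.z_coords, moving.z_coords
        expected = []
        for i, z in enumerate(fz):
            if mz.min() - 1.0 <= z <= mz.max() + 1.0:  # dz/2 = 1.0
                d = np.abs(mz - z)
                expected.append((i, int(np.flatnonzero(d == d.min())[0])))
        assert [(p.fixed_index, p.moving_index) for p in pairs] == expected


# -- 8-bit evaluation convention ---------------------------------------------

def test_uint8_quantization_rules():
    assert to_eval_uint8(np.array([0.0]))[0] == 0
    assert to_eval_uint8(np.array([1.0]))[0] == 255
    assert to_eval_uint8(np.array([0.5]))[0] == 128  # round half away from zero
    with pytest.raises(ValueError, match="\\[0,1\\]"):
        to_eval_uint8(np.array([1.5]))


def test_uint8_idempotence():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    again = to_eval_uint8(from_eval_uint8(img))
    assert (again == img).all()


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.0, max_value=1.0))
def test_windowing_monotone_and_quantization_order_preserving(a, b):
    """For any unit values a <= b, windowing preserved their order and the
    8-bit quantizer never swaps them."""
    lo, hi = sorted((a, b))
    va = window_normalize(_vol(np.full((1, 1, 1), -160 + 400 * lo))).voxels.item()
    vb = window_normalize(_vol(np.full((1, 1, 1), -160 + 400 * hi))).voxels.item()
    assert va <= vb + 1e-12
    qa = to_eval_uint8(np.array([lo]))[0]
    qb = to_eval_uint8(np.array([hi]))[0]
    assert qa <= qb
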