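"""Shared fixtures: phantoms, extracted meshes, and a DICOM fixture writer."""

from __future__ import annotations

import numpy as np
import pytest

from ctrecon import mc
from ctrecon.phantoms import PhantomSpec, make_slice_image, make_volume


@pytest.fixture(scope="session")
def sphere_phantom():
    """64^3 sphere of radius 20 voxels, the reference reconstruction target."""
    return make_volume(PhantomSpec(kind="sphere", dims=(64, 64, 64), radii=20.0))


@pytest.fixture(scope="session")
def sphere_mesh(sphere_phantom):
    return mc.extract_isosurface(sphere_phantom.volume, sphere_phantom.isovalue)


@pytest.fixture(scope="session")
def liver_phantom():
    """Flat liver-like blob used for slice rendering and smoothing tests."""
    return make_volume(
        PhantomSpec(kind="liver-like-blob", dims=(64, 64, 8), radii=(14.0, 10.0, 2.5))
    )


@pytest.fixture(scope="session")
def liver_slices():
    spec = PhantomSpec(kind="liver-like-blob", dims=(64, 64, 8), radii=(14.0, 10.0, 2.5))
    return [make_slice_image(spec, k) for k in (2, 3, 4, 5)]


def write_dicom_slice(path, rows, cols, k, pixel_values, *, spacing=(1.0, 1.0), gap=2.0):
    """Write one synthetic single-frame CT slice usable by the series reader."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = "1.2.3.4"
    ds.Modality = "CT"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [spacing[1], spacing[0]]  # (row, col)
    ds.ImagePositionPatient = [0.0, 0.0, k * gap]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.InstanceNumber = k + 1
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.asarray(pixel_values, dtype=np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)
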