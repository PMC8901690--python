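"""Shared fixtures: synthetic speckle fields, LV phantoms and DICOM cines.

All fixtures are generated programmatically with fixed seeds; expensive
phantom sequences are session-scoped so the suite builds each condition
once.
"""

import numpy as np
import pytest

from ltcstrain.synthetic_phantom import AffineTruth, affine_sequence, lv_phantom, make_speckle_field


@pytest.fixture(scope="session")
def speckle_field():
    """257x257 clean speckle texture used by the spectral-kernel tests."""
    return make_speckle_field((257, 257), density=0.08, diameter=3.0, seed=1)


@pytest.fixture(scope="session")
def scaled_pair_factory(speckle_field):
    """Factory: speckle frame pair with an imposed vertical stretch a22."""
    def _make(a22, a11=1.0):
        seq, truth = affine_sequence(speckle_field, AffineTruth(a11=[a11], a22=[a22]), 2)
        return seq.frames[0], seq.frames[1], truth
    return _make


@pytest.fixture(scope="session")
def phantom_cnr8():
    """Clean-ish LV phantom (CNR 8, 20 frames) with ground truth."""
    return lv_phantom(peak_strain=-15.0, n_frames=20, frame_interval=0.02, cnr=8.0, seed=3)


@pytest.fixture(scope="session")
def phantom_cnr2():
    """Heavy-clutter LV phantom (CNR 2) with ground truth."""
    return lv_phantom(peak_strain=-15.0, n_frames=20, frame_interval=0.02, cnr=2.0, seed=3)


def write_synthetic_dicom(path, frames, frame_time_ms=20.0, color=False, drop_timing=False):
    """Write a synthetic multi-frame ultrasound DICOM fixture."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ds = Dataset()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UltrasoundMultiFrameImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = frames.shape[1:3]
    ds.NumberOfFrames = frames.shape[0]
    if not drop_timing:
        ds.FrameTime = str(frame_time_ms)
    if color:
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        arr = np.repeat(frames[..., None], 3, axis=-1)
    else:
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        arr = frames
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = arr.astype(np.uint8).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
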