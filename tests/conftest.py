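import numpy as np
import pytest

from bonegraphcut import GraphCutParams, PhantomSpec, STGraph, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with no noise (sub-pixel default blur)."""
    spec = PhantomSpec(noise_sd=0.0)
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def crisp_phantom():
    """Phantom with neither blur nor noise: exactly piecewise constant."""
    spec = PhantomSpec(noise_sd=0.0, blur_sigma=0.0)
    image, truth = generate_phantom(spec)
    return spec, image, truth


def random_stgraph(rng, height, width, integer=True, connectivity=8):
    """A random s-t grid graph, built directly (independent of build_graph)."""
    n = height * width
    idx = np.arange(n).reshape(height, width)
    pairs = []
    offsets = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 8 else [])
    for dr, dc in offsets:
        for r in range(height):
            for c in range(width):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < height and 0 <= c2 < width:
                    p, q = idx[r, c], idx[r2, c2]
                    pairs.append((min(p, q), max(p, q)))
    if integer:
        draw = lambda size: rng.integers(0, 11, size=size).astype(float)
    else:
        draw = lambda size: rng.random(size)
    return STGraph(
        height=height,
        width=width,
        t_link_source=draw(n),
        t_link_sink=draw(n),
        link_p=np.array([p for p, _ in pairs], dtype=np.int64),
        link_q=np.array([q for _, q in pairs], dtype=np.int64),
        link_cap=draw(len(pairs)),
        params=GraphCutParams(connectivity=connectivity),
    )


def write_test_dicom(path, stored, slope=1.0, intercept=0.0):
    """Write a minimal single-frame grayscale DICOM fixture."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    stored = np.asarray(stored, dtype=np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
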