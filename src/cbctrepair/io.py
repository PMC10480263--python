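"""Volume I/O: NIfTI files and single-frame DICOM series.

NIfTI stores HU as float32 (lossless round-trip); DICOM is written with
explicit rescale tags (stored uint16, intercept -1024) and read back through
slope/intercept, refusing files without calibration metadata. Slices are
ordered by their axial position.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .phantom import CTVolume


def write_volume(vol: CTVolume, path: str | Path, format: str = "nifti") -> None:
    path = Path(path)
    if format == "nifti":
        affine = np.diag([1.0, 1.0, vol.slice_thickness, 1.0])
        # store (H, W, n) so the slice axis is the NIfTI third axis
        img = nib.Nifti1Image(np.transpose(vol.data, (1, 2, 0)).astype(np.float32), affine)
        nib.save(img, str(path))
    elif format == "dicom":
        path.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid()
        for i in range(len(vol)):
            _write_dicom_slice(vol, i, series_uid, path / f"slice_{i:04d}.dcm")
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_dicom_slice(vol: CTVolume, i: int, series_uid: str, fname: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(fname), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = series_uid
    ds.PatientID = vol.patient_id
    ds.Modality = "CT"
    ds.Rows, ds.Columns = vol.data.shape[1:]
    ds.InstanceNumber = i + 1
    ds.SliceThickness = vol.slice_thickness
    ds.ImagePositionPatient = [0.0, 0.0, float(i * vol.slice_thickness)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [1.0, 1.0]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    stored = np.clip(np.rint(vol.data[i] + 1024.0), 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(fname), enforce_file_format=True)


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI or a DICOM series directory.

    HU calibration (rescale slope/intercept) is applied for DICOM; missing
    calibration raises rather than returning raw stored values.
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format == "nifti":
        img = nib.load(str(path))
        data = np.transpose(np.asarray(img.dataobj, dtype=np.float32), (2, 0, 1))
        thickness = float(img.header.get_zooms()[2])
        return CTVolume(data, thickness, patient_id=path.stem)
    if format == "dicom":
        files = sorted(os.listdir(path))
        datasets = []
        for f in files:
            if not f.lower().endswith(".dcm"):
                continue
            ds = pydicom.dcmread(str(path / f))
            if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
                raise ValueError(f"{f}: missing HU rescale metadata")
            datasets.append(ds)
        if not datasets:
            raise ValueError(f"no DICOM files in {path}")
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        slices = [
            d.pixel_array.astype(np.float32) * float(d.RescaleSlope) + float(d.RescaleIntercept)
            for d in datasets
        ]
        thickness = float(datasets[0].SliceThickness)
        return CTVolume(np.stack(slices), thickness, patient_id=str(datasets[0].PatientID))
    raise ValueError(f"unknown format {format!r}")
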