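"""Volume containers and readers/writers.

World coordinates are millimetres in the DICOM patient frame (LPS: +x left,
+y posterior, +z superior) with 0-based voxel indices and voxel centres at
integer indices.  NIfTI files store RAS affines, so the first two axes are
sign-flipped on read and write; the flip is recorded in the provenance.  All
module math downstream is frame-agnostic given the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import MsemapError

__all__ = ["ScanSeries", "read_volume", "write_nifti", "write_dicom_series",
           "write_deformation_nifti"]

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ScanSeries:
    """One acquisition: voxels plus a voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray
    series_id: int = 0
    is_center: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4):
            raise MsemapError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MsemapError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


def read_volume(path: str | Path, series_id: int = 0, is_center: bool = False) -> ScanSeries:
    """Read a NIfTI file or a DICOM series directory into a ScanSeries (LPS mm)."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, series_id, is_center)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        affine = _RAS_TO_LPS @ img.affine
        data = np.asanyarray(img.dataobj)
        return ScanSeries(
            data, affine, series_id, is_center,
            provenance={"source": str(path), "format": "nifti",
                        "ras_to_lps_flips": [-1, -1, 1]},
        )
    raise MsemapError(f"unrecognized volume path {path} (expect .nii[.gz] or a DICOM dir)")


def write_nifti(scan: ScanSeries, path: str | Path) -> None:
    """Write a ScanSeries to NIfTI, converting the LPS affine back to RAS."""
    img = nib.Nifti1Image(np.asarray(scan.voxels), _RAS_TO_LPS @ scan.affine)
    nib.save(img, str(path))


def write_deformation_nifti(displacement: np.ndarray, affine: np.ndarray,
                            path: str | Path) -> None:
    """Write a 3-component displacement volume (mm, LPS components) to NIfTI.

    ``displacement`` has shape (nx, ny, nz, 3) in the apparent-coordinate
    convention (displacement sign = segmented - designed).
    """
    img = nib.Nifti1Image(np.asarray(displacement, np.float32),
                          _RAS_TO_LPS @ np.asarray(affine, float))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ["ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing",
                  "Rows", "Columns"]


def _read_dicom_series(directory: Path, series_id: int, is_center: bool) -> ScanSeries:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # skip non-DICOM files
    if not datasets:
        raise MsemapError(f"no DICOM slices found in {directory}")
    missing = sorted({tag for ds in datasets for tag in _REQUIRED_TAGS if tag not in ds})
    if missing:
        raise MsemapError(f"DICOM series missing spatial tags: {missing}")
    iop0 = np.asarray(datasets[0].ImageOrientationPatient, float)
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop0, atol=1e-6):
            raise MsemapError("mixed-orientation DICOM slices in series")
    col_dir, row_dir = iop0[:3], iop0[3:]
    normal = np.cross(col_dir, row_dir)
    positions = np.array([np.asarray(ds.ImagePositionPatient, float) for ds in datasets])
    order = np.argsort(positions @ normal, kind="stable")
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    along = positions @ normal
    gaps = np.diff(along)
    if len(gaps):
        step = np.median(gaps)
        bad = np.flatnonzero(~np.isclose(gaps, step, rtol=1e-3, atol=1e-3))
        if len(bad):
            raise MsemapError(
                f"non-uniform DICOM slice spacing: gap after sorted slice {bad[0]} "
                f"is {gaps[bad[0]]:.4f} mm vs median {step:.4f} mm (missing slice?)"
            )
    else:
        step = float(getattr(datasets[0], "SliceThickness", 1.0))

    dr, dc = (float(v) for v in datasets[0].PixelSpacing)  # (row spacing, col spacing)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # voxel index (i, j, k) = (column, row, slice)
    vol = np.transpose(np.stack(slices, axis=0), (2, 1, 0))
    affine = np.eye(4)
    affine[:3, 0] = col_dir * dc
    affine[:3, 1] = row_dir * dr
    affine[:3, 2] = normal * step
    affine[:3, 3] = positions[0]
    return ScanSeries(vol, affine, series_id, is_center,
                      provenance={"source": str(directory), "format": "dicom",
                                  "n_slices": len(datasets)})


def write_dicom_series(scan: ScanSeries, directory: str | Path,
                       series_description: str = "msemap synthetic") -> None:
    """Write a minimal single-frame DICOM series (one file per slice).

    Intensities are scaled to uint16 with RescaleSlope/Intercept; the affine
    must have orthogonal columns (true for the synthetic scans this package
    renders).  Intended for interoperability tests, not clinical use.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    A = scan.affine[:3, :3]
    dc, dr, dsl = np.linalg.norm(A, axis=0)
    col_dir, row_dir, normal = A[:, 0] / dc, A[:, 1] / dr, A[:, 2] / dsl
    if not (abs(col_dir @ row_dir) < 1e-6 and abs(col_dir @ normal) < 1e-6):
        raise MsemapError("DICOM export requires an orthogonal affine")
    vol = np.asarray(scan.voxels, float)
    vmin, vmax = float(vol.min()), float(vol.max())
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    series_uid = generate_uid(entropy_srcs=[f"msemap-{scan.series_id}"])
    for k in range(vol.shape[2]):
        sl = np.round((vol[:, :, k] - vmin) / slope).astype(np.uint16)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"msemap-{scan.series_id}-{k}"])
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesDescription = series_description
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = int(scan.series_id)
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*(float(v) for v in col_dir),
                                      *(float(v) for v in row_dir)]
        pos = scan.affine[:3, 3] + k * A[:, 2]
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.PixelSpacing = [float(dr), float(dc)]
        ds.SliceThickness = float(dsl)
        ds.Rows, ds.Columns = sl.T.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = float(slope)
        ds.RescaleIntercept = float(vmin)
        ds.PixelData = sl.T.tobytes()
        ds.save_as(str(directory / f"slice_{k:04d}.dcm"),
                   enforce_file_format=True)
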