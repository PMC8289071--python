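"""Reading, writing and canonical orientation of CT volumes.

A :class:`CTVolume` stores Hounsfield-unit voxels on a regular grid with
axis order ``(z, y, x)`` in a fixed anatomical frame:

* ``z`` increases toward *superior* (head),
* ``y`` increases toward *anterior* (front),
* ``x`` increases toward *subject-left*.

All downstream modules (segmentation, landmark detection, contouring)
assume this frame, so every reader canonicalizes on load.  Physical
position of a voxel is ``index * spacing`` (slice-center convention,
0-based indices).

Supported containers are NIfTI-1 files (via nibabel) and directories
holding a single single-frame CT DICOM series (via pydicom, with
RescaleSlope/Intercept applied so voxels are HU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import DataError

HU_PLAUSIBLE_RANGE = (-1500.0, 4000.0)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units on the canonical (z, y, x) grid.

    Parameters
    ----------
    voxels:
        3D float32 array of HU values, axis order (z, y, x).
    spacing:
        Physical voxel spacing (dz, dy, dx) in millimetres, all > 0.
    source:
        Free-text provenance (file path or synthetic identifier).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source: str = "<memory>"
    canonical: bool = field(default=True)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise DataError(f"expected a 3D voxel array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be three positive values, got {self.spacing}")
        lo, hi = HU_PLAUSIBLE_RANGE
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        if vmin < lo or vmax > hi:
            warnings.warn(
                f"HU values outside plausible range [{lo}, {hi}]: "
                f"observed [{vmin:.0f}, {vmax:.0f}]",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI file or a DICOM series directory into canonical frame.

    DICOM slices are sorted by physical z position (ascending, i.e.
    inferior to superior) regardless of file order, and rescale
    slope/intercept are applied so voxels are Hounsfield units.

    Raises
    ------
    DataError
        If the path does not exist, spacing metadata is missing, or the
        directory mixes multiple DICOM series.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a canonical CTVolume as NIfTI-1 with a spacing/orientation affine.

    The voxel array is stored so that ``read_volume`` round-trips voxels,
    spacing and orientation exactly.
    """
    path = Path(path)
    dz, dy, dx = vol.spacing
    # File axes (i, j, k) = (x, y, z) of the canonical array.  Canonical x
    # points to subject-left = -R, so the RAS affine negates the first axis.
    data = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0))
    affine = np.diag([-dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, str(path))
    except OSError as exc:  # unwritable path
        raise DataError(f"cannot write volume to {path}: {exc}") from exc


def _read_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise DataError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # RAS+: i->right, j->anterior, k->superior
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise DataError(f"missing or invalid voxel spacing in {path}")
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    # RAS (x, y, z) -> canonical (z, y, x-left): transpose then flip x.
    data = data.transpose(2, 1, 0)[:, :, ::-1]
    # NIfTI pixdim is float32; round to 1e-6 mm so decimal spacings
    # (0.7, 1.5, ...) survive the write/read round trip exactly
    dx, dy, dz = (round(float(z), 6) for z in zooms)
    return CTVolume(np.ascontiguousarray(data), (dz, dy, dx), source=str(path))


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR stubs)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise DataError(f"no DICOM images found in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise DataError(f"directory {path} mixes {len(uids)} DICOM series")

    def z_pos(ds) -> float:
        if not hasattr(ds, "ImagePositionPatient"):
            raise DataError("DICOM slice lacks ImagePositionPatient")
        return float(ds.ImagePositionPatient[2])

    datasets.sort(key=z_pos)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise DataError("DICOM series lacks PixelSpacing metadata")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    zs = np.array([z_pos(ds) for ds in datasets])
    if len(zs) > 1:
        dz_arr = np.diff(zs)
        if np.any(dz_arr <= 0):
            raise DataError("duplicate or non-monotonic DICOM slice positions")
        dz = float(np.mean(dz_arr))
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise DataError("cannot determine slice spacing for single-slice series")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # Patient coords are LPS; pixel rows run anterior->posterior, columns
    # right->left.  Canonical y is anterior-up, so flip rows; columns
    # already increase toward subject-left; z sort above is inferior->superior.
    data = np.stack(slices, axis=0)[:, ::-1, :]
    return CTVolume(np.ascontiguousarray(data), (dz, row_mm, col_mm), source=str(path))
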