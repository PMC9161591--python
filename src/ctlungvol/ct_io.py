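"""Reading and writing CT volumes, masks and label maps.

NIfTI files are handled with nibabel and DICOM series with pydicom.  On
disk NIfTI data are stored in ``(x, y, z)`` order with a diagonal affine
built from the voxel spacing; in memory the package uses ``(z, y, x)``
with ``z=0`` superior, so arrays are transposed on the way in and out.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import FormatError, SpacingError
from .image import CTVolume, Mask3D, RegionLabelMap, DEFAULT_LABELS

__all__ = [
    "load_ct",
    "load_nifti_ct",
    "load_dicom_series",
    "save_nifti",
    "load_label_map",
]

_SLICE_GAP_RTOL = 1e-3


def load_ct(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom"``; when omitted it is
    inferred: directories are DICOM series, files are NIfTI.
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format == "nifti":
        return load_nifti_ct(path)
    if format == "dicom":
        return load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def load_nifti_ct(path: str | Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    # stored (x, y, z) -> package (z, y, x)
    return CTVolume(np.ascontiguousarray(data.T), (zooms[2], zooms[1], zooms[0]))


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Stack a single-series DICOM directory into HU, superior slice first."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no files in DICOM directory {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise FormatError(f"no image slices in {directory}")
    try:
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]), reverse=True)
        zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
        py, px = (float(v) for v in slices[0].PixelSpacing)
    except AttributeError as exc:
        raise FormatError(f"missing geometry tags in {directory}: {exc}") from exc

    if len(slices) > 1:
        gaps = -np.diff(zs)
        dz = float(np.median(gaps))
        bad = np.flatnonzero(np.abs(gaps - dz) > _SLICE_GAP_RTOL * dz)
        if bad.size:
            k = int(bad[0])
            raise SpacingError(
                f"non-uniform slice spacing: gap {gaps[k]:.4f} mm between "
                f"slices {k} and {k + 1} (expected {dz:.4f} mm)"
            )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    hu = np.stack(
        [
            d.pixel_array.astype(np.float32) * float(getattr(d, "RescaleSlope", 1.0))
            + float(getattr(d, "RescaleIntercept", 0.0))
            for d in slices
        ]
    )
    return CTVolume(hu, (dz, py, px))


def save_nifti(
    obj: CTVolume | Mask3D | RegionLabelMap, path: str | Path
) -> None:
    """Write a volume, mask or label map as NIfTI with matching geometry."""
    if isinstance(obj, CTVolume):
        data = obj.intensities.astype(np.float32)
    elif isinstance(obj, Mask3D):
        data = obj.data.astype(np.uint8)
    else:
        data = obj.data.astype(np.int16)
    dz, dy, dx = obj.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def load_label_map(
    path: str | Path, labels: dict[str, int] | None = None
) -> RegionLabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return RegionLabelMap(
        np.ascontiguousarray(data.T).astype(np.int16),
        (zooms[2], zooms[1], zooms[0]),
        labels=dict(labels or DEFAULT_LABELS),
    )
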