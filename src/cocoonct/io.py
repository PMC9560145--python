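"""Volume input/output.

NIfTI is the canonical on-disk format; DICOM series are supported read-only
(slope/intercept rescaled to true HU).  In memory every volume is a numpy
array indexed ``(z, y, x)`` with the voxel spacing carried alongside in
millimetres per axis, in the same order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pydicom


@dataclass
class VolumeMeta:
    """Geometry and provenance of a volume."""

    voxel_spacing: tuple[float, float, float]  # mm per (z, y, x) axis
    shape: tuple[int, int, int]
    intensity_units: str = "HU"  # "HU" or "normalized"
    source: str = "synthetic"  # "nifti" | "dicom_series" | "synthetic"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")


def write_volume(path: str | os.PathLike, volume: np.ndarray, meta: VolumeMeta) -> None:
    """Write a (z, y, x) volume as NIfTI with spacing recorded in the header."""
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    sz, sy, sx = meta.voxel_spacing
    # NIfTI stores (x, y, z); transpose so the header spacing lines up.
    data = np.transpose(volume, (2, 1, 0))
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, VolumeMeta]:
    """Read a NIfTI file or a DICOM series directory into (z, y, x) order.

    DICOM pixel data are converted to Hounsfield units via the mandatory
    RescaleSlope / RescaleIntercept tags; their absence is an error rather
    than a silent identity rescale.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    sx, sy, sz = img.header.get_zooms()[:3]
    vol = np.transpose(data, (2, 1, 0))
    meta = VolumeMeta(voxel_spacing=(float(sz), float(sy), float(sx)),
                      shape=vol.shape, intensity_units="HU", source="nifti")
    return vol, meta


def write_probability_volume(path: str | os.PathLike, probs: np.ndarray,
                             meta: VolumeMeta) -> None:
    """Write a (C, z, y, x) per-class probability volume as 4D NIfTI."""
    if probs.ndim != 4:
        raise ValueError("expected a (C, z, y, x) probability volume")
    sz, sy, sx = meta.voxel_spacing
    data = np.transpose(probs, (3, 2, 1, 0))  # -> (x, y, z, C)
    img = nib.Nifti1Image(data.astype(np.float32), np.diag([sx, sy, sz, 1.0]))
    nib.save(img, os.fspath(path))


def read_probability_volume(path: str | os.PathLike) -> tuple[np.ndarray, VolumeMeta]:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4D probability NIfTI")
    sx, sy, sz = img.header.get_zooms()[:3]
    probs = np.transpose(data, (3, 2, 1, 0))
    meta = VolumeMeta(voxel_spacing=(float(sz), float(sy), float(sx)),
                      shape=probs.shape[1:], intensity_units="normalized", source="nifti")
    return probs, meta


def _read_dicom_series(directory: str) -> tuple[np.ndarray, VolumeMeta]:
    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) > 1:
        raise ValueError("mixed DICOM series: multiple SeriesInstanceUID values found")

    def _z(s):
        pos = getattr(s, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(s, "InstanceNumber", 0))

    slices.sort(key=_z)
    planes = []
    for s in slices:
        if "RescaleSlope" not in s or "RescaleIntercept" not in s:
            missing = "RescaleSlope" if "RescaleSlope" not in s else "RescaleIntercept"
            raise ValueError(f"DICOM slice missing required tag {missing} (0028,1053/0028,1052)")
        planes.append(s.pixel_array.astype(np.float32) * float(s.RescaleSlope)
                      + float(s.RescaleIntercept))
    vol = np.stack(planes, axis=0)
    first = slices[0]
    py, px = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1:
        dz = abs(_z(slices[1]) - _z(slices[0])) or float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    meta = VolumeMeta(voxel_spacing=(dz, py, px), shape=vol.shape,
                      intensity_units="HU", source="dicom_series")
    return vol, meta
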