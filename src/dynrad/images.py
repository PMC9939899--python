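"""Image volumes, ROI masks and NRRD/DICOM I/O (via SimpleITK).

Voxel arrays are stored in ``(z, y, x)`` index order (the SimpleITK /
numpy convention) with ``spacing`` and ``origin`` given as ``(x, y, z)``
millimetres, matching the NRRD header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["PHASES", "ImageVolume", "RoiMask", "read_volume", "write_volume", "read_mask"]

log = logging.getLogger("dynrad")

#: canonical acquisition-phase order of a four-phase abdominal CECT study
PHASES = ("PP", "AP", "PVP", "DP")


@dataclass
class ImageVolume:
    """A single-phase CT volume in Hounsfield units."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxels must be finite-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if len(set(self.spacing)) > 1:
            log.info("non-isotropic spacing %s", self.spacing)


@dataclass
class RoiMask:
    """Binary region-of-interest mask companion to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels) > 0.5
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        if not self.voxels.any():
            raise ValueError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _from_sitk(img: sitk.Image, phase: str | None) -> ImageVolume:
    return ImageVolume(
        voxels=sitk.GetArrayFromImage(img).astype(float),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        phase=phase,
    )


def _to_sitk(vol: ImageVolume | RoiMask) -> sitk.Image:
    arr = vol.voxels.astype(np.uint8) if isinstance(vol, RoiMask) else vol.voxels
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def read_volume(path: str | Path, phase: str | None = None, series_id: str | None = None) -> ImageVolume:
    """Read an NRRD file or a single-series DICOM directory.

    Parameters
    ----------
    path : str or Path
        Either an NRRD file or a directory containing one DICOM series.
    series_id : str, optional
        Required to disambiguate a directory holding multiple series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        ids = reader.GetGDCMSeriesIDs(str(path))
        if not ids:
            raise ValueError(f"no DICOM series found in {path}")
        if series_id is None:
            if len(ids) > 1:
                raise ValueError(
                    f"{path} contains {len(ids)} DICOM series; pass series_id "
                    f"(one of {list(ids)})"
                )
            series_id = ids[0]
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path), series_id))
        return _from_sitk(reader.Execute(), phase)
    return _from_sitk(sitk.ReadImage(str(path)), phase)


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary ROI mask from NRRD."""
    img = sitk.ReadImage(str(path))
    return RoiMask(
        voxels=sitk.GetArrayFromImage(img),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(vol: ImageVolume | RoiMask, path: str | Path) -> None:
    """Write a volume or mask to NRRD (format from the file extension)."""
    sitk.WriteImage(_to_sitk(vol), str(Path(path)))
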