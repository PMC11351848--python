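"""3D medical volume container and NIfTI/NRRD I/O.

All of :mod:`coroseg` uses a single in-memory currency: a :class:`Volume`
holding a 3D scalar array indexed ``(z, y, x)`` (axis 0 = axial slice index)
together with per-axis voxel spacing and world origin in millimetres.
Intensities are kept as floating point regardless of the on-disk scalar type,
because the downstream stages (diffusion denoising, normalization,
vesselness) are continuous-valued.

SimpleITK backs the on-disk formats (NIfTI-1 ``.nii``/``.nii.gz`` and NRRD
``.nrrd``). SimpleITK's array view is already (z, y, x); its spacing/origin
tuples are (x, y, z) and are reversed here. The direction (orientation)
matrix is carried opaquely so a read–write round trip preserves it, but it is
never interpreted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "Mask", "read_volume", "write_volume"]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd")


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and origin metadata.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``. Stored as float unless the caller
        explicitly passes another dtype (masks use uint8).
    spacing:
        Per-axis voxel size in mm, ``(z, y, x)`` order, strictly positive.
    origin:
        World coordinate (mm) of voxel ``(0, 0, 0)``, ``(z, y, x)`` order.
    direction:
        Opaque 9-element row-major direction cosine matrix in ITK (x, y, z)
        convention; preserved on write, never interpreted.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: Tuple[float, ...] = field(
        default=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3-dimensional, got rank {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"every axis must have size >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype(self, dtype) -> "Volume":
        return replace(self, data=self.data.astype(dtype))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this one's spatial metadata."""
        return replace(self, data=data)


class Mask(Volume):
    """A binary (0/1) volume aligned to an intensity :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)


def _check_ext(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_EXT):
        raise IOError(
            f"unsupported volume format for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI or NRRD volume, keeping intensities unmodified.

    Raises
    ------
    IOError
        If the file is missing or not a readable NIfTI/NRRD image.
    ValueError
        If the image on disk is not rank 3 (e.g. a 2D slice or 4D series).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path!r}")
    _check_ext(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # unreadable / wrong format
        raise IOError(f"could not read {path!r} as NIfTI/NRRD: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(
            f"expected a 3D image, found rank {img.GetDimension()} in {path!r}"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(
        data=data, spacing=spacing, origin=origin, direction=tuple(img.GetDirection())
    )


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write ``vol`` to NIfTI or NRRD; the format follows the extension."""
    path = os.fspath(path)
    _check_ext(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    img.SetDirection(vol.direction)
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc


def as_mask(vol: Volume) -> Mask:
    """Reinterpret a 0/1-valued Volume as a Mask (validates values)."""
    return Mask(
        data=vol.data, spacing=vol.spacing, origin=vol.origin, direction=vol.direction
    )
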