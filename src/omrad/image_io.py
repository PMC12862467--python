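"""Volumes, masks and grid handling.

Coordinate convention (used everywhere in the package): voxel arrays are
indexed ``voxels[i, j, k]`` with axis 0 -> physical x, axis 1 -> y and
axis 2 -> z; voxel indices are 0-based and the physical position of a
voxel centre is ``origin + index * spacing`` (mm).  SimpleITK stores
arrays in (z, y, x) order, so readers/writers transpose accordingly.

All band geometry and feature extraction downstream assume an isotropic
grid; :func:`resample_isotropic` (default target 1.0 mm) makes millimetre
band widths coincide with voxel steps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DimensionalityError, FormatError, PairingError, ParameterError

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar image with physical spacing and origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise DimensionalityError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("volume contains non-finite intensities")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ParameterError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    def same_grid(self, other: "VolumeGrid | MaskVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class MaskVolume:
    """A binary region sharing the :class:`VolumeGrid` geometry.

    ``voxels`` is boolean internally; any {0,1}-valued input is accepted.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DimensionalityError(f"expected a 3D mask, got shape {v.shape}")
        if v.dtype != bool:
            vals = np.unique(v)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError(f"mask values must be binary, found {vals[:10]}")
            v = v.astype(bool)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ParameterError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def physical_volume(self) -> float:
        """Mask volume in mm^3 (voxel count x voxel volume)."""
        return self.voxel_count * float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid | MaskVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def require_same_grid(a, b, what: str = "volume and mask") -> None:
    """Raise :class:`PairingError` unless *a* and *b* share shape/spacing/origin."""
    if not a.same_grid(b):
        raise PairingError(
            f"{what} do not share a grid: shapes {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing}"
        )


def _read_sitk(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    if not str(path).endswith(_SUPPORTED_EXT):
        raise FormatError(f"unsupported image format (need NIfTI or NRRD): {path}")
    try:
        return sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise FormatError(f"could not read {path}: {exc}") from exc


def read_volume(path: str) -> VolumeGrid:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) scalar volume.

    Spacing and origin are taken from the header; intensities are not
    modified.  4D or 2D images are rejected.
    """
    img = _read_sitk(path)
    if img.GetDimension() != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return VolumeGrid(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def read_mask(path: str, companion: VolumeGrid | None = None) -> MaskVolume:
    """Read a binary mask; optionally check pairing against its image."""
    vol = read_volume(path)
    mask = MaskVolume(vol.voxels, vol.spacing, vol.origin)
    if companion is not None:
        require_same_grid(companion, mask, "image and mask")
    return mask


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_volume(vol: VolumeGrid, path: str) -> None:
    """Write to NIfTI or NRRD based on the file extension."""
    if not str(path).endswith(_SUPPORTED_EXT):
        raise FormatError(f"unsupported output format: {path}")
    sitk.WriteImage(_to_sitk(vol.voxels, vol.spacing, vol.origin), str(path))


def write_mask(mask: MaskVolume, path: str) -> None:
    if not str(path).endswith(_SUPPORTED_EXT):
        raise FormatError(f"unsupported output format: {path}")
    sitk.WriteImage(
        _to_sitk(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), str(path)
    )


def resample_isotropic(vol, target_mm: float = 1.0, mode: str = "continuous"):
    """Resample a volume or mask to an isotropic grid.

    Output extent per axis is ``round(extent * spacing / target_mm)``.
    ``mode='continuous'`` uses trilinear interpolation (images);
    ``mode='nearest'`` preserves the value set (masks).  A grid already
    isotropic at the target is returned unchanged.
    """
    if target_mm <= 0:
        raise ParameterError(f"target_mm must be positive, got {target_mm}")
    if mode not in ("continuous", "nearest"):
        raise ParameterError(f"mode must be 'continuous' or 'nearest', got {mode!r}")
    spacing = np.asarray(vol.spacing, dtype=float)
    if np.allclose(spacing, target_mm):
        return vol
    is_mask = isinstance(vol, MaskVolume)
    data = vol.voxels.astype(np.float32) if is_mask else vol.voxels
    zoom = spacing / target_mm
    out_shape = tuple(int(round(e * z)) for e, z in zip(vol.shape, zoom))
    order = 0 if mode == "nearest" else 1
    out = ndimage.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode zoom matches round(extent*zoom) shape; guard against drift
    if out.shape != out_shape:  # pragma: no cover
        out = out[tuple(slice(0, s) for s in out_shape)]
    new = (target_mm,) * 3
    if is_mask:
        return MaskVolume(out.astype(bool), new, vol.origin)
    return replace(vol, voxels=out, spacing=new)
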