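"""NIfTI volume I/O and Jacobian-determinant post-processing.

The analysis consumes Jacobian determinant maps: voxelwise factors of the
volumetric expansion/contraction needed to warp an individual brain to a
common template. Before entering the models, each map is smoothed with a
Gaussian kernel (8 mm FWHM by default), log-transformed to remove skewness,
linearly rescaled so that the global minimum/maximum over the whole dataset
map to 0/1, and masked so non-brain voxels are exactly zero. The chain is
applied in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "FWHM_TO_SIGMA",
    "JacobianVolume",
    "BrainMask",
    "VolumeIOError",
    "MissingVolumeError",
    "NonVolumetricImageError",
    "HeaderReadError",
    "InvalidJacobianError",
    "DegenerateScaleError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "gaussian_smooth",
    "log_transform",
    "scale_dataset_unit_interval",
    "apply_mask",
    "preprocess_chain",
]

#: FWHM / sigma for a Gaussian: 2 * sqrt(2 * ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

STAGES = ("raw", "smoothed", "logged", "scaled")


class VolumeIOError(Exception):
    """Base class for volume reading/processing failures."""


class MissingVolumeError(VolumeIOError, FileNotFoundError):
    """The requested NIfTI file does not exist."""


class NonVolumetricImageError(VolumeIOError):
    """The NIfTI file does not contain a 3-D image."""


class HeaderReadError(VolumeIOError):
    """The file exists but its header could not be parsed as NIfTI."""


class InvalidJacobianError(VolumeIOError):
    """A non-positive in-brain Jacobian value, which has no physical meaning."""


class DegenerateScaleError(VolumeIOError):
    """Unit-interval scaling is undefined when all in-mask values are equal."""


@dataclass(frozen=True)
class JacobianVolume:
    """A single subject's 3-D Jacobian determinant map.

    ``stage`` tracks progress through the post-processing chain
    (raw -> smoothed -> logged -> scaled).
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    stage: str = "raw"

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise NonVolumetricImageError(f"expected a 3-D grid, got ndim={v.ndim}")
        if min(v.shape) < 1:
            raise ValueError("all dims must be strictly positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        object.__setattr__(self, "voxels", v)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class BrainMask:
    """Binary in-brain indicator grid; must select at least one voxel."""

    voxels: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voxels).astype(bool)
        if v.ndim != 3:
            raise NonVolumetricImageError(f"mask must be 3-D, got ndim={v.ndim}")
        if not v.any():
            raise ValueError("mask selects no voxels")
        object.__setattr__(self, "voxels", v)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _affine_from_voxel_size(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def read_volume(path, subject_id: str = "", stage: str = "raw") -> JacobianVolume:
    """Read a 3-D NIfTI-1 image into a :class:`JacobianVolume`.

    Values are not modified; dims and voxel size come from the header.
    """
    path = Path(path)
    if not path.exists():
        raise MissingVolumeError(str(path))
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
    except MissingVolumeError:
        raise
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise HeaderReadError(f"{path}: {exc}") from exc
    if data.ndim != 3:
        raise NonVolumetricImageError(
            f"{path}: expected 3-D image, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in zooms[:3])
    if subject_id == "":
        subject_id = path.name.split(".")[0]
    return JacobianVolume(data, voxel_size_mm=voxel_size,
                          subject_id=subject_id, stage=stage)


def write_volume(v: JacobianVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float64),
                          _affine_from_voxel_size(v.voxel_size_mm))
    img.header.set_zooms(v.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(vol.voxels > 0.5)


def write_mask(m: BrainMask, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(m.voxels.astype(np.uint8),
                          _affine_from_voxel_size(voxel_size_mm))
    nib.save(img, str(path))


def gaussian_smooth(v: JacobianVolume, fwhm_mm: float = 8.0) -> JacobianVolume:
    """Separable Gaussian smoothing; per-axis sigma = FWHM / (2*sqrt(2 ln 2)) / voxel size.

    The field outside the grid is treated as zero.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    if any(s is None or s <= 0 for s in v.voxel_size_mm):
        raise ValueError("voxel size unknown or non-positive")
    sigma = [fwhm_mm / FWHM_TO_SIGMA / s for s in v.voxel_size_mm]
    out = ndimage.gaussian_filter(v.voxels, sigma=sigma, mode="constant", cval=0.0)
    return replace(v, voxels=out, stage="smoothed")


def log_transform(v: JacobianVolume, mask: BrainMask | None = None) -> JacobianVolume:
    """Natural log, voxelwise. In-brain values must be strictly positive.

    Without a mask every voxel must be positive. With a mask, non-positive
    out-of-brain voxels (e.g. exact zeros in empty space) are mapped to 0.
    """
    x = v.voxels
    if mask is None:
        if np.any(x <= 0):
            raise InvalidJacobianError("non-positive voxel value; not a valid Jacobian")
        out = np.log(x)
    else:
        if mask.dims != v.dims:
            raise ValueError(f"mask dims {mask.dims} != volume dims {v.dims}")
        if np.any(x[mask.voxels] <= 0):
            raise InvalidJacobianError("non-positive in-mask Jacobian value")
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.log(x[pos])
    return replace(v, voxels=out, stage="logged")


def scale_dataset_unit_interval(
    volumes: list[JacobianVolume], mask: BrainMask | None = None,
) -> list[JacobianVolume]:
    """Map the single global [min, max] over all volumes linearly onto [0, 1].

    One shared affine is applied to every volume, so values stay comparable
    across the dataset; min/max are taken over in-mask voxels when a mask is
    given. Idempotent once applied.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    if mask is not None:
        for v in volumes:
            if mask.dims != v.dims:
                raise ValueError(f"mask dims {mask.dims} != volume dims {v.dims}")
        lo = min(float(v.voxels[mask.voxels].min()) for v in volumes)
        hi = max(float(v.voxels[mask.voxels].max()) for v in volumes)
    else:
        lo = min(float(v.voxels.min()) for v in volumes)
        hi = max(float(v.voxels.max()) for v in volumes)
    if hi == lo:
        raise DegenerateScaleError("all in-mask values identical; cannot scale")
    scale = 1.0 / (hi - lo)
    return [replace(v, voxels=(v.voxels - lo) * scale, stage="scaled")
            for v in volumes]


def apply_mask(v: JacobianVolume, m: BrainMask) -> JacobianVolume:
    """Zero out-of-mask voxels; in-mask voxels are untouched."""
    if m.dims != v.dims:
        raise ValueError(f"mask dims {m.dims} != volume dims {v.dims}")
    out = np.where(m.voxels, v.voxels, 0.0)
    return replace(v, voxels=out)


def preprocess_chain(
    volumes: list[JacobianVolume], mask: BrainMask, fwhm_mm: float = 8.0,
) -> list[JacobianVolume]:
    """Full deterministic chain: smooth, log, unit-scale (dataset-wide), mask."""
    smoothed = [gaussian_smooth(v, fwhm_mm) for v in volumes]
    logged = [log_transform(v, mask) for v in smoothed]
    scaled = scale_dataset_unit_interval(logged, mask)
    return [apply_mask(v, mask) for v in scaled]
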