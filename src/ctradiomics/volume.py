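"""Volumes, ROI masks and gray-level discretization.

A planning-CT stand-in is a 3D scalar array with anisotropic voxel spacing
carried separately (all geometry in mm).  Arrays are indexed ``(x, y, z)``
with 0-based indices.  The region of interest is a congruent binary mask
(the clinical target volume in the radiotherapy use case).  Texture-matrix
features operate on an integer relabelling of the in-mask intensities into
``1..Ng`` gray levels produced by :func:`discretize`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelVolume",
    "ROIMask",
    "DiscretizedROI",
    "GeometryError",
    "EmptyROIError",
    "DataError",
    "load_volume_and_mask",
    "save_volume",
    "discretize",
]


class GeometryError(ValueError):
    """Volume/mask shapes or spacings are inconsistent."""


class EmptyROIError(ValueError):
    """The mask selects no voxels."""


class DataError(ValueError):
    """Voxel data contains non-finite values."""


@dataclass
class VoxelVolume:
    """3D scalar grid with anisotropic spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units emulating HU).
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, each strictly positive.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive floats, got {self.spacing}")
        self.origin = tuple(float(s) for s in self.origin)
        if not np.isfinite(self.data).all():
            raise DataError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class ROIMask:
    """Binary region of interest congruent with a :class:`VoxelVolume`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {m.shape}")
        # > 0 binarization tolerates probabilistic or integer-label masks
        self.mask = m > 0
        if not self.mask.any():
            raise EmptyROIError("mask selects no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscretizedROI:
    """Integer gray-level relabelling of in-mask voxels.

    ``levels`` is 0 outside the mask and in ``1..n_levels`` inside.
    ``degenerate`` flags a constant-intensity ROI (every voxel at level 1).
    """

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inside = self.levels > 0
        if not inside.any():
            raise EmptyROIError("discretized ROI is empty")
        lv = self.levels[inside]
        if lv.min() < 1 or lv.max() > self.n_levels:
            raise ValueError("in-mask levels must lie in [1, n_levels]")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def _read_image(path: str) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd/.nhdr) image."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return data, zooms, origin
    if lower.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).T.astype(float)
        return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    raise ValueError(f"unsupported image format: {path}")


def save_volume(path: str, data: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D array as NIfTI with the given spacing/origin (mm)."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)


def load_volume_and_mask(volume_path: str, mask_path: str, rtol: float = 1e-3) -> tuple[VoxelVolume, ROIMask]:
    """Load a volume and its ROI mask, validating geometric congruence.

    Raises
    ------
    GeometryError
        If shapes differ or spacings disagree beyond ``rtol`` relative.
    EmptyROIError
        If the binarized (> 0) mask selects no voxels.
    DataError
        If the volume contains non-finite voxels.
    """
    vdata, vspacing, vorigin = _read_image(volume_path)
    mdata, mspacing, _ = _read_image(mask_path)
    if vdata.shape != mdata.shape:
        raise GeometryError(f"volume shape {vdata.shape} != mask shape {mdata.shape}")
    if not np.allclose(vspacing, mspacing, rtol=rtol, atol=0.0):
        raise GeometryError(f"volume spacing {vspacing} != mask spacing {mspacing}")
    return VoxelVolume(vdata, vspacing, vorigin), ROIMask(mdata)


def discretize(
    volume: VoxelVolume,
    mask: ROIMask,
    n_bins: int = 64,
    mode: str = "relative",
    bounds: tuple[float, float] | None = None,
) -> DiscretizedROI:
    """Bin in-mask intensities into ``1..n_bins`` equal-width gray levels.

    ``relative`` mode spans the in-mask min–max (the maximum falls in bin
    ``n_bins``); ``absolute`` mode uses caller ``bounds``, clamping
    out-of-range intensities into the end bins.  A constant-intensity ROI is
    legal: every voxel gets level 1 and ``degenerate`` is set.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if volume.shape != mask.shape:
        raise GeometryError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown discretization mode {mode!r}")

    vals = volume.data[mask.mask]
    if mode == "relative":
        lo, hi = float(vals.min()), float(vals.max())
    else:
        if bounds is None:
            raise ValueError("absolute mode requires bounds=(lo, hi)")
        lo, hi = float(bounds[0]), float(bounds[1])
        if lo >= hi:
            raise ValueError(f"absolute bounds must satisfy lo < hi, got {bounds}")

    levels = np.zeros(volume.shape, dtype=np.int64)
    degenerate = False
    if hi == lo:
        levels[mask.mask] = 1
        degenerate = True
        edges = np.array([lo, lo + 1.0])
    else:
        x = np.clip(vals, lo, hi)
        lv = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[mask.mask] = lv
        edges = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
    return DiscretizedROI(
        levels=levels,
        n_levels=n_bins,
        bin_edges=edges,
        degenerate=degenerate,
        meta={"mode": mode, "lo": lo, "hi": hi},
    )
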