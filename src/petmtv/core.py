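"""Volume/mask data model, NIfTI I/O, resampling and SUV conversion.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``[x, y, z]`` with 0-based voxel indices.
* Axes: ``x`` runs patient left -> right, ``y`` anterior -> posterior,
  ``z`` inferior -> superior (so "superior pole" means the largest z).
* World coordinates are millimetres on an axis-aligned grid:
  ``world = origin + index * spacing`` (voxel centres).
* Voxel volume is ``sx * sy * sz / 1000`` cm^3.

CT values are Hounsfield units, PET values are body-weight SUV (g/mL).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator

import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError

__all__ = [
    "ORGAN_LABELS",
    "ORGAN_NAMES",
    "VoxelGrid",
    "ImageVolume",
    "BinaryMask",
    "OrganMaskSet",
    "voxel_volume_cm3",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "to_suv",
    "resample_mask",
]

#: Integer label map used for multi-organ NIfTI label volumes.
ORGAN_LABELS = {
    "brain": 1,
    "heart": 2,
    "kidney_left": 3,
    "kidney_right": 4,
    "bladder": 5,
}
ORGAN_NAMES = tuple(ORGAN_LABELS)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned 3-D sampling grid (shape, spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def extent(self, axis: int) -> tuple[float, float]:
        """Physical extent (mm) covered by the voxels along one axis."""
        lo = self.origin[axis] - 0.5 * self.spacing[axis]
        hi = self.origin[axis] + (self.shape[axis] - 0.5) * self.spacing[axis]
        return lo, hi


def voxel_volume_cm3(grid: VoxelGrid) -> float:
    """Volume of a single voxel in cm^3 (``sx*sy*sz/1000``)."""
    return grid.voxel_volume_cm3


@dataclass
class ImageVolume:
    """A scalar 3-D image (CT in HU or PET in SUV) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray
    modality: str = "CT"  # {"CT", "PET"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.modality not in ("CT", "PET"):
            raise ValueError(f"modality must be CT or PET, got {self.modality!r}")


@dataclass
class BinaryMask:
    """A boolean region on a :class:`VoxelGrid` (organ or lesion)."""

    grid: VoxelGrid
    membership: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not self.membership.any()


@dataclass
class OrganMaskSet:
    """Binary masks for the five physiologically avid structures, one grid."""

    brain: BinaryMask
    heart: BinaryMask
    kidney_left: BinaryMask
    kidney_right: BinaryMask
    bladder: BinaryMask

    def __post_init__(self) -> None:
        grids = {m.grid for m in self}
        if len(grids) != 1:
            raise GeometryError("all organ masks must share one grid")

    def __iter__(self) -> Iterator[BinaryMask]:
        for name in ORGAN_NAMES:
            yield getattr(self, name)

    @property
    def grid(self) -> VoxelGrid:
        return self.brain.grid

    def union(self) -> BinaryMask:
        out = np.zeros(self.grid.shape, dtype=bool)
        for m in self:
            out |= m.membership
        return BinaryMask(self.grid, out, label="organs")

    def check_disjoint(self) -> None:
        total = sum(m.voxel_count for m in self)
        if total != self.union().voxel_count:
            raise GeometryError("organ masks overlap")

    def to_label_map(self) -> np.ndarray:
        """Integer label volume using :data:`ORGAN_LABELS` (0 = background)."""
        out = np.zeros(self.grid.shape, dtype=np.uint8)
        for name, lab in ORGAN_LABELS.items():
            out[getattr(self, name).membership] = lab
        return out

    @classmethod
    def from_label_map(cls, grid: VoxelGrid, labels: np.ndarray) -> "OrganMaskSet":
        labels = np.asarray(labels)
        if labels.shape != grid.shape:
            raise GeometryError("label map shape does not match grid")
        masks = {
            name: BinaryMask(grid, labels == lab, label=name)
            for name, lab in ORGAN_LABELS.items()
        }
        return cls(**masks)


# ---------------------------------------------------------------------------
# File I/O (NIfTI primary; DICOM series optional via SimpleITK)
# ---------------------------------------------------------------------------

def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VoxelGrid(tuple(int(n) for n in img.shape[:3]), zooms, origin)


def read_volume(path: str | os.PathLike, modality: str = "CT") -> ImageVolume:
    """Read a 3-D NIfTI volume.

    The image is reoriented to the closest canonical axis order so that the
    array follows the package convention (x, y, z with z superior).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"expected a 3-D image, got {img.ndim}-D: {path}")
    img = nib.as_closest_canonical(img)
    values = np.asarray(img.dataobj)
    return ImageVolume(_grid_from_nifti(img), values, modality=modality)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal (axis-aligned) affine."""
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.values), affine), str(path))


def read_label_map(path: str | os.PathLike) -> tuple[VoxelGrid, np.ndarray]:
    """Read an integer label volume (organ/lesion labels)."""
    vol = read_volume(path, modality="CT")
    return vol.grid, np.asarray(np.rint(vol.values), dtype=np.int32)


def write_label_map(grid: VoxelGrid, labels: np.ndarray, path: str | os.PathLike) -> None:
    write_volume(ImageVolume(grid, np.asarray(labels, dtype=np.uint8)), path)


def read_dicom_series(directory: str | os.PathLike, modality: str = "CT") -> ImageVolume:
    """Read a DICOM series through SimpleITK (optional input path).

    Returns the volume with SimpleITK's (x, y, z) ordering mapped onto the
    package convention. PET series are returned in their stored units; use
    :func:`to_suv` with the dose/weight metadata for SUV conversion.
    """
    import SimpleITK as sitk  # local import: optional code path

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FileNotFoundError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    grid = VoxelGrid(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return ImageVolume(grid, values, modality=modality)


# ---------------------------------------------------------------------------
# SUV conversion and resampling
# ---------------------------------------------------------------------------

def to_suv(activity: ImageVolume, injected_dose_bq: float, body_weight_g: float) -> ImageVolume:
    """Convert an activity-concentration PET volume (Bq/mL) to body-weight SUV.

    SUV = C / (dose / weight), i.e. each voxel is multiplied by
    ``weight / dose``. The dose must already be decay-corrected to scan start.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be > 0 Bq, got {injected_dose_bq}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be > 0 g, got {body_weight_g}")
    suv = np.asarray(activity.values, dtype=np.float64) * (body_weight_g / injected_dose_bq)
    return ImageVolume(activity.grid, suv, modality="PET")


def _nearest_indices(target: VoxelGrid, source: VoxelGrid, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest source index for every target voxel centre along one axis."""
    tw = target.axis_coords(axis)
    idx = np.rint((tw - source.origin[axis]) / source.spacing[axis]).astype(np.int64)
    valid = (idx >= 0) & (idx < source.shape[axis])
    return np.clip(idx, 0, source.shape[axis] - 1), valid


def resample_mask(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Resample a binary mask onto another grid by nearest neighbour.

    Each target voxel takes the value of the nearest source voxel centre in
    world coordinates; target voxels outside the source extent are False.
    """
    src = mask.grid
    if src == target:
        return BinaryMask(target, mask.membership.copy(), label=mask.label)
    for ax in range(3):
        slo, shi = src.extent(ax)
        tlo, thi = target.extent(ax)
        if shi <= tlo or thi <= slo:
            raise GeometryError(
                f"source and target grids are physically disjoint on axis {ax}"
            )
    ix, vx = _nearest_indices(target, src, 0)
    iy, vy = _nearest_indices(target, src, 1)
    iz, vz = _nearest_indices(target, src, 2)
    out = mask.membership[np.ix_(ix, iy, iz)]
    out &= vx[:, None, None] & vy[None, :, None] & vz[None, None, :]
    return BinaryMask(target, out, label=mask.label)
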