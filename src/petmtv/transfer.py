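"""Adaptation of CT-derived organ contours to their PET presentation.

Organ boundaries on PET differ from CT (spill-over from the point-spread
function, physiologic motion, tracer distribution), so each CT mask is
adjusted on the PET grid before it is excluded from the MTV analysis
space: the mask is resampled to the PET grid, eroded to a conservative
seed region, and grown over 26-connected voxels whose SUV exceeds a
fraction of the organ's robust peak uptake, never beyond a dilated margin
around the original contour. An optional fast-marching front (SimpleITK)
can refine the grown region with a speed map derived from SUV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, ORGAN_NAMES, OrganMaskSet, resample_mask
from .errors import GeometryError

__all__ = ["TransferParams", "transfer_contours", "analysis_space"]


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the CT-to-PET contour adjustment.

    ``dilation_margin_mm`` bounds how far the PET mask may extend beyond
    the CT contour; ``erosion_mm`` shrinks the contour to seed voxels;
    the region-growing threshold is ``uptake_fraction`` times the organ's
    95th-percentile SUV inside the resampled CT contour.
    """

    dilation_margin_mm: float = 12.0
    erosion_mm: float = 4.0
    uptake_fraction: float = 0.5
    peak_percentile: float = 95.0
    background_factor: float = 2.0
    refinement: str = "none"  # {"none", "fast_marching"}
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.dilation_margin_mm < 0 or self.erosion_mm < 0:
            raise ValueError("margins must be nonnegative")
        if not 0.0 < self.uptake_fraction < 1.0:
            raise ValueError("uptake fraction must be in (0, 1)")
        if self.background_factor <= 0:
            raise ValueError("background factor must be positive")
        if self.refinement not in ("none", "fast_marching"):
            raise ValueError(f"unknown refinement mode {self.refinement!r}")


def ball_footprint(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element covering ``radius_mm`` in world units."""
    r_vox = [max(int(np.floor(radius_mm / s)), 0) for s in spacing]
    if all(r == 0 for r in r_vox):
        return np.ones((1, 1, 1), dtype=bool)
    ax = [np.arange(-r, r + 1) * s for r, s in zip(r_vox, spacing)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    return d2 <= radius_mm ** 2


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])


def _fast_marching_region(pet: ImageVolume, seeds: np.ndarray,
                          constraint: np.ndarray, threshold: float,
                          margin_mm: float) -> np.ndarray:
    """Voxels reachable from the seeds by a fast-marching front.

    The front moves with speed proportional to local SUV (normalized by the
    growth threshold), so avid tissue is absorbed quickly while cold voxels
    slow the front; arrival times up to the dilation margin (at unit speed)
    are accepted.
    """
    import SimpleITK as sitk

    speed_arr = np.maximum(pet.values / max(threshold, 1e-6), 1e-3)
    # SimpleITK expects (z, y, x)
    speed = sitk.GetImageFromArray(
        np.ascontiguousarray(speed_arr.transpose(2, 1, 0), dtype=np.float64))
    speed.SetSpacing(tuple(pet.grid.spacing))
    fm = sitk.FastMarchingImageFilter()
    # after the (2,1,0) transpose above, SimpleITK's (x,y,z) index order
    # coincides with the package's array indices
    fm.SetTrialPoints([(int(x), int(y), int(z)) for x, y, z in zip(*np.nonzero(seeds))])
    fm.SetStoppingValue(float(margin_mm) * 2.0)
    arrival = sitk.GetArrayFromImage(fm.Execute(speed)).transpose(2, 1, 0)
    return (arrival <= margin_mm) & constraint


def _transfer_one(mask_ct: BinaryMask, pet: ImageVolume,
                  params: TransferParams,
                  background_suv: float) -> tuple[BinaryMask, np.ndarray | None]:
    """Returns (adjusted mask, sorted SUVs inside the CT contour or None)."""
    grid = pet.grid
    m = resample_mask(mask_ct, grid)
    if m.is_empty():
        return BinaryMask(grid, np.zeros(grid.shape, bool), label=mask_ct.label), None
    inside = pet.values[m.membership]
    peak = float(np.percentile(inside, params.peak_percentile))
    # follow organ spill-over down to near-background: the inclusion
    # threshold is the lesser of a fraction of the organ's robust peak and
    # a multiple of the surrounding background level, so the whole PET
    # presentation of an avid organ (point-spread halo included) is
    # absorbed while cold surroundings are not
    threshold = min(params.uptake_fraction * peak,
                    params.background_factor * background_suv)
    threshold = max(threshold, 1e-9)

    seeds = ndimage.binary_erosion(m.membership,
                                   structure=ball_footprint(params.erosion_mm, grid.spacing))
    if not seeds.any():
        seeds = m.membership.copy()  # organ smaller than the erosion kernel
    constraint = ndimage.binary_dilation(
        m.membership, structure=ball_footprint(params.dilation_margin_mm, grid.spacing))

    supra = pet.values >= threshold
    supra_seeds = seeds & supra
    if not supra_seeds.any():
        warnings.warn(
            f"{mask_ct.label or 'organ'}: no supra-threshold seed voxels; "
            "keeping the resampled CT contour unchanged")
        return BinaryMask(grid, m.membership, label=mask_ct.label), np.sort(inside)

    comp, _ = ndimage.label(supra & constraint, structure=_structure(params.connectivity))
    keep = np.unique(comp[supra_seeds])
    grown = np.isin(comp, keep[keep > 0])
    if params.refinement == "fast_marching":
        grown |= _fast_marching_region(pet, supra_seeds, constraint, threshold,
                                       params.dilation_margin_mm)
    grown |= seeds
    return BinaryMask(grid, grown, label=mask_ct.label), np.sort(inside)


def transfer_contours(organs_ct: OrganMaskSet, pet: ImageVolume,
                      params: TransferParams | None = None) -> OrganMaskSet:
    """Adjust all five CT organ contours to the PET grid.

    Where two adjusted masks overlap, each contested voxel is assigned to
    the organ in whose uptake distribution it ranks higher (percentile of
    the voxel SUV within the organ's CT-contour SUVs).
    """
    params = params or TransferParams()
    resampled = np.zeros(pet.grid.shape, dtype=bool)
    for name in ORGAN_NAMES:
        resampled |= resample_mask(getattr(organs_ct, name), pet.grid).membership
    outside = pet.values[~resampled]
    background_suv = float(np.median(outside)) if outside.size else float(np.min(pet.values))
    results: dict[str, BinaryMask] = {}
    dists: dict[str, np.ndarray | None] = {}
    for name in ORGAN_NAMES:
        results[name], dists[name] = _transfer_one(
            getattr(organs_ct, name), pet, params, background_suv)

    # resolve overlaps
    names = list(ORGAN_NAMES)
    claim = np.zeros(pet.grid.shape, dtype=np.int8)
    for mask in results.values():
        claim += mask.membership
    contested = np.argwhere(claim > 1)
    for vox in contested:
        v = float(pet.values[tuple(vox)])
        best_name, best_rank = None, -1.0
        for name in names:
            if not results[name].membership[tuple(vox)]:
                continue
            d = dists[name]
            rank = np.searchsorted(d, v, side="right") / d.size if d is not None else 0.0
            if rank > best_rank:
                best_name, best_rank = name, rank
        for name in names:
            if name != best_name:
                results[name].membership[tuple(vox)] = False
    return OrganMaskSet(**results)


def analysis_space(pet: ImageVolume, organs_pet: OrganMaskSet,
                   body_threshold: float = 0.0) -> BinaryMask:
    """The MTV analysis space: whole imaged volume minus the organ masks.

    With ``body_threshold > 0`` only voxels whose SUV exceeds the threshold
    (a crude body contour) are analyzable; the default keeps the whole grid.
    """
    if organs_pet.grid != pet.grid:
        raise GeometryError("organ masks must live on the PET grid")
    if body_threshold > 0:
        space = pet.values > body_threshold
    else:
        space = np.ones(pet.grid.shape, dtype=bool)
    space = space & ~organs_pet.union().membership
    return BinaryMask(pet.grid, space, label="analysis_space")
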