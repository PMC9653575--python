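"""Automated metabolic tumor volume (MTV) determination on FDG-PET.

The algorithm works on the PET volume after the physiologically avid
organs (brain, heart, kidneys, bladder) have been excluded:

1. A narrow trapezoid-shaped exclusion zone is built between the superior
   poles of the kidneys and the central cross-sectional plane of the
   bladder. Its per-slice rectangle interpolates linearly between a top
   base spanning the two kidney midlines (x) and the combined kidney
   anterior/posterior extent (y), and a bottom base spanning the
   bladder's lateral and anterior/posterior borders in its central
   plane. The zone catches ureter uptake and stray urinary activity that
   the organ masks miss.
2. The remaining volume is thresholded at 41% of its SUVmax, contiguous
   supra-threshold voxels are clustered (26-connectivity by default),
   clusters larger than 1 cm^3 become candidate lesions, and candidates
   are screened out if smaller than 2 cm^3 or if they fall in the zone.
3. If the cluster containing the SUVmax voxel was screened out, its
   voxels are removed from the analysis space and the process repeats
   with the next SUVmax, so each successive threshold is strictly lower.

The reported MTV is the summed volume of the retained lesions; the
reported SUVmax is the maximum SUV within them (the global maximum over
the analysis space is kept alongside in the result).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, OrganMaskSet, VoxelGrid
from .errors import DegenerateInputError, EmptySpaceError
from .transfer import analysis_space

__all__ = [
    "MTVParams",
    "TrapezoidZone",
    "LesionROI",
    "MTVResult",
    "build_exclusion_zone",
    "global_suvmax",
    "cluster_suprathreshold",
    "screen_candidates",
    "compute_mtv",
]


@dataclass(frozen=True)
class MTVParams:
    """Thresholding/screening parameters of the automated MTV algorithm.

    Defaults follow the method as published: threshold at 41% of SUVmax,
    clusters kept as candidates when strictly larger than 1 cm^3, screened
    out when strictly smaller than 2 cm^3; a cluster "falls in" the
    trapezoid zone when more than ``zone_fraction`` of its voxels do.
    """

    threshold_fraction: float = 0.41
    candidate_min_cm3: float = 1.0  # strict >
    lesion_min_cm3: float = 2.0  # screened if strictly <
    connectivity: int = 26
    zone_rule: str = "majority"  # {"majority", "any_overlap", "centroid"}
    zone_fraction: float = 0.5  # strict >, for the majority rule
    max_iterations: int = 100
    body_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold fraction must be in (0, 1)")
        if self.candidate_min_cm3 > self.lesion_min_cm3:
            raise ValueError("candidate minimum must not exceed lesion minimum")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.zone_rule not in ("majority", "any_overlap", "centroid"):
            raise ValueError(f"unknown zone rule {self.zone_rule!r}")


@dataclass
class TrapezoidZone:
    """The realized urinary exclusion zone plus its defining geometry."""

    mask: BinaryMask
    z_top: int
    z_bottom: int
    top_bounds: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    bottom_bounds: tuple[float, float, float, float]

    def bounds_at(self, z: int) -> tuple[float, float, float, float]:
        """Linearly interpolated rectangle bounds in voxel coordinates."""
        if self.z_top == self.z_bottom:
            return self.top_bounds
        t = (z - self.z_bottom) / (self.z_top - self.z_bottom)
        return tuple(b + t * (a - b)
                     for a, b in zip(self.top_bounds, self.bottom_bounds))


@dataclass(eq=False)
class LesionROI:
    """One candidate lesion: mask, volume, peak uptake and screening status."""

    mask: BinaryMask
    volume_cm3: float
    suvmax: float
    suvmax_voxel: tuple[int, int, int]
    status: str = "retained"  # {retained, screened_small, screened_zone, screened_candidate}

    @property
    def centroid_voxel(self) -> tuple[float, float, float]:
        idx = np.argwhere(self.mask.membership)
        c = idx.mean(axis=0)
        return (float(c[0]), float(c[1]), float(c[2]))


@dataclass
class IterationRecord:
    iteration: int
    suvmax: float
    threshold: float
    removed_volume_cm3: float | None
    removed_status: str | None


@dataclass
class MTVResult:
    mtv_cm3: float
    suvmax: float | None
    suvmax_voxel: tuple[int, int, int] | None
    retained: list[LesionROI]
    screened: list[LesionROI]
    trace: list[IterationRecord]
    global_suvmax: float | None
    zone: TrapezoidZone | None

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


# ---------------------------------------------------------------------------
# Zone geometry
# ---------------------------------------------------------------------------

def _centroid(mask: np.ndarray, axis: int) -> float:
    other = tuple(a for a in range(3) if a != axis)
    counts = mask.sum(axis=other).astype(np.float64)
    coords = np.arange(mask.shape[axis], dtype=np.float64)
    return float((coords * counts).sum() / counts.sum())


def build_exclusion_zone(kidney_left: BinaryMask, kidney_right: BinaryMask,
                         bladder: BinaryMask, grid: VoxelGrid | None = None
                         ) -> TrapezoidZone:
    """Construct the trapezoid urinary exclusion zone on the PET grid.

    Extends from the superior pole of the kidneys (most superior kidney
    voxel) down to the bladder's central cross-sectional plane (rounded
    z-centroid of the bladder mask). Top base: x between the two kidney
    x-centroids (midlines), y over the combined kidney extent. Bottom
    base: the bladder's x/y bounding extents in its central plane. The
    per-slice rectangles interpolate the four bounds linearly in z.
    """
    for name, m in (("kidney_left", kidney_left), ("kidney_right", kidney_right),
                    ("bladder", bladder)):
        if m.is_empty():
            raise ValueError(f"build_exclusion_zone: {name} mask is empty")
    grid = grid or bladder.grid
    kl, kr, bl = kidney_left.membership, kidney_right.membership, bladder.membership

    z_top = int(max(np.flatnonzero(kl.any(axis=(0, 1)))[-1],
                    np.flatnonzero(kr.any(axis=(0, 1)))[-1]))
    z_bottom = int(round(_centroid(bl, 2)))
    if z_bottom > z_top:
        raise DegenerateInputError(
            f"bladder central plane (z={z_bottom}) lies above the kidneys' "
            f"superior pole (z={z_top})")

    kx_left = _centroid(kl, 0)
    kx_right = _centroid(kr, 0)
    ky_idx = np.flatnonzero(kl.any(axis=(0, 2)) | kr.any(axis=(0, 2)))
    top = (min(kx_left, kx_right), max(kx_left, kx_right),
           float(ky_idx[0]), float(ky_idx[-1]))

    bl_plane = bl[:, :, z_bottom]
    if not bl_plane.any():  # centroid plane can miss a concave mask
        zs = np.flatnonzero(bl.any(axis=(0, 1)))
        z_bottom = int(zs[np.argmin(np.abs(zs - z_bottom))])
        bl_plane = bl[:, :, z_bottom]
    bx = np.flatnonzero(bl_plane.any(axis=1))
    by = np.flatnonzero(bl_plane.any(axis=0))
    bottom = (float(bx[0]), float(bx[-1]), float(by[0]), float(by[-1]))

    mask = np.zeros(grid.shape, dtype=bool)
    zone = TrapezoidZone(BinaryMask(grid, mask, label="trapezoid_zone"),
                         z_top=z_top, z_bottom=z_bottom,
                         top_bounds=top, bottom_bounds=bottom)
    for z in range(z_bottom, z_top + 1):
        x0, x1, y0, y1 = zone.bounds_at(z)
        mask[int(round(x0)):int(round(x1)) + 1,
             int(round(y0)):int(round(y1)) + 1, z] = True
    return zone


# ---------------------------------------------------------------------------
# Thresholding and clustering
# ---------------------------------------------------------------------------

def global_suvmax(pet: ImageVolume, space: BinaryMask
                  ) -> tuple[float, tuple[int, int, int]]:
    """Maximum SUV over the analysis space; ties break to the smallest
    linear (C-order) voxel index for determinism."""
    if space.grid != pet.grid:
        raise ValueError("analysis space must live on the PET grid")
    if space.is_empty():
        raise EmptySpaceError("no analyzable voxels")
    masked = np.where(space.membership, pet.values, -np.inf)
    flat = int(np.argmax(masked))
    loc = np.unravel_index(flat, pet.grid.shape)
    return float(pet.values[loc]), (int(loc[0]), int(loc[1]), int(loc[2]))


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def cluster_suprathreshold(pet: ImageVolume, space: BinaryMask, threshold: float,
                           connectivity: int = 26) -> list[LesionROI]:
    """Connected components of supra-threshold (>=) voxels inside the space."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    supra = space.membership & (pet.values >= threshold)
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    voxvol = pet.grid.voxel_volume_cm3
    out: list[LesionROI] = []
    for ci in range(1, n + 1):
        m = labels == ci
        vals = np.where(m, pet.values, -np.inf)
        flat = int(np.argmax(vals))
        loc = np.unravel_index(flat, pet.grid.shape)
        out.append(LesionROI(
            mask=BinaryMask(pet.grid, m, label=f"cluster_{ci}"),
            volume_cm3=float(m.sum()) * voxvol,
            suvmax=float(pet.values[loc]),
            suvmax_voxel=(int(loc[0]), int(loc[1]), int(loc[2])),
        ))
    return out


def _in_zone(roi: LesionROI, zone: TrapezoidZone | None, params: MTVParams) -> bool:
    if zone is None or zone.mask.is_empty():
        return False
    inside = int((roi.mask.membership & zone.mask.membership).sum())
    if params.zone_rule == "any_overlap":
        return inside > 0
    if params.zone_rule == "centroid":
        c = tuple(int(round(v)) for v in roi.centroid_voxel)
        return bool(zone.mask.membership[c])
    return inside / roi.mask.voxel_count > params.zone_fraction


def screen_candidates(candidates: list[LesionROI], zone: TrapezoidZone | None,
                      params: MTVParams) -> tuple[list[LesionROI], list[LesionROI]]:
    """Split candidate clusters into retained lesions and screened-out ones.

    Candidates smaller than the lesion minimum (strict <) become
    ``screened_small``; candidates falling in the trapezoid zone become
    ``screened_zone``; everything else is retained.
    """
    retained, screened = [], []
    for roi in candidates:
        if roi.volume_cm3 < params.lesion_min_cm3:
            roi.status = "screened_small"
            screened.append(roi)
        elif _in_zone(roi, zone, params):
            roi.status = "screened_zone"
            screened.append(roi)
        else:
            roi.status = "retained"
            retained.append(roi)
    return retained, screened


# ---------------------------------------------------------------------------
# The iterative loop
# ---------------------------------------------------------------------------

def _empty_result(zone: TrapezoidZone | None, trace: list[IterationRecord],
                  global_max: float | None = None) -> MTVResult:
    return MTVResult(mtv_cm3=0.0, suvmax=None, suvmax_voxel=None, retained=[],
                     screened=[], trace=trace, global_suvmax=global_max, zone=zone)


def compute_mtv(pet: ImageVolume, organs_pet: OrganMaskSet,
                params: MTVParams | None = None,
                zone: TrapezoidZone | None = None) -> MTVResult:
    """Run the full iterative threshold/cluster/screen loop.

    ``zone`` is built from the organ masks when not supplied (and skipped
    with a degenerate-geometry warning if kidneys or bladder are empty).
    Returns MTV = 0 with an empty lesion list when the analysis space is
    empty or contains no positive uptake.
    """
    params = params or MTVParams()
    if zone is None:
        if (organs_pet.kidney_left.is_empty() or organs_pet.kidney_right.is_empty()
                or organs_pet.bladder.is_empty()):
            zone = None
        else:
            zone = build_exclusion_zone(organs_pet.kidney_left,
                                        organs_pet.kidney_right,
                                        organs_pet.bladder, pet.grid)

    space0 = analysis_space(pet, organs_pet, body_threshold=params.body_threshold)
    removed = np.zeros(pet.grid.shape, dtype=bool)
    trace: list[IterationRecord] = []
    screened_all: list[LesionROI] = []
    global_max: float | None = None

    for it in range(1, params.max_iterations + 1):
        space = BinaryMask(pet.grid, space0.membership & ~removed, label="space")
        if space.is_empty():
            return _empty_result(zone, trace, global_max)
        smax, loc = global_suvmax(pet, space)
        if global_max is None:
            global_max = smax
        if smax <= 0:
            return _empty_result(zone, trace, global_max)
        threshold = params.threshold_fraction * smax
        clusters = cluster_suprathreshold(pet, space, threshold, params.connectivity)
        candidates = [c for c in clusters if c.volume_cm3 > params.candidate_min_cm3]
        retained, screened = screen_candidates(candidates, zone, params)

        hot = next(c for c in clusters if c.mask.membership[loc])
        if hot in retained:
            trace.append(IterationRecord(it, smax, threshold, None, None))
            screened_all.extend(screened)
            best = max(retained, key=lambda r: r.suvmax)
            return MTVResult(
                mtv_cm3=float(sum(r.volume_cm3 for r in retained)),
                suvmax=best.suvmax,
                suvmax_voxel=best.suvmax_voxel,
                retained=retained,
                screened=screened_all + [],
                trace=trace,
                global_suvmax=global_max,
                zone=zone,
            )
        # the hottest cluster was screened out (or was not even a candidate):
        # remove its voxels from the analysis space and re-threshold
        if hot not in candidates:
            hot.status = "screened_candidate"
        removed |= hot.mask.membership
        screened_all.append(hot)
        trace.append(IterationRecord(it, smax, threshold, hot.volume_cm3, hot.status))

    raise DegenerateInputError(
        f"MTV loop did not converge within {params.max_iterations} iterations")
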