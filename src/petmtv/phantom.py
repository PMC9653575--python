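"""Synthetic whole-body FDG-PET/CT phantom generator.

Each phantom is a paired CT/PET volume on one grid with ground-truth organ
masks (brain, heart, both kidneys, bladder), spherical lesions of known
voxelized volume, optional ureter-like tubes of focal uptake running from
the kidneys to the bladder, and the resulting true metabolic tumor volume
(MTV). Organs are ellipsoids, lesions spheres, ureters capsules — enough
geometry to exercise segmentation, contour transfer, the urinary exclusion
zone and the MTV loop, with no pretence of anatomical realism.

Truth masks are voxelized *before* the optional PSF blur and noise are
applied: blur models the scanner response, not anatomy, so the ground truth
stays unambiguous.

Default uptake values are typical body-weight SUV magnitudes for an FDG
study (background soft tissue ~1, brain ~7, myocardium ~5, renal
parenchyma/pelvis ~6, bladder urine ~15, avid lymphoma ~8). CT organ values
are noise-free synthetic constants chosen pairwise distinct so that the
organ classes are well posed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    BinaryMask,
    ImageVolume,
    ORGAN_NAMES,
    OrganMaskSet,
    VoxelGrid,
    write_label_map,
    write_volume,
)
from .errors import GenerationError

__all__ = [
    "OrganSpec",
    "LesionSpec",
    "UreterSpec",
    "PhantomSpec",
    "PhantomCase",
    "CohortVariation",
    "default_phantom_spec",
    "generate_phantom",
    "iter_cohort",
    "generate_cohort",
    "labeled_case",
    "write_case",
]


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: centre/radii in mm, CT value in HU, PET in SUV."""

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    ct_hu: float
    pet_suv: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise GenerationError(f"organ {self.name}: radii must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: centre/radius in mm, PET uptake in SUV."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake_suv: float
    ct_hu: float = 25.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise GenerationError("lesion radius must be > 0")


@dataclass(frozen=True)
class UreterSpec:
    """Thin tubes of urinary uptake from each kidney's inferior pole to the bladder."""

    radius_mm: float = 3.0
    suv: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid
    background_suv: float
    background_hu: float
    organs: tuple[OrganSpec, ...]
    lesions: tuple[LesionSpec, ...] = ()
    ureter: UreterSpec | None = None
    blur_fwhm_mm: float = 0.0
    noise_sigma_suv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if sorted(names) != sorted(ORGAN_NAMES):
            raise GenerationError(f"organs must be exactly {ORGAN_NAMES}, got {names}")
        om = {o.name: o for o in self.organs}
        kl, kr, bl = om["kidney_left"], om["kidney_right"], om["bladder"]
        if not kl.center_mm[0] < kr.center_mm[0]:
            raise GenerationError("left kidney centre must have smaller x than right")
        if not min(kl.center_mm[2], kr.center_mm[2]) > bl.center_mm[2]:
            raise GenerationError("kidneys must be superior (larger z) to the bladder centre")
        for o in self.organs:
            for ax in range(3):
                lo, hi = self.grid.extent(ax)
                if o.center_mm[ax] - o.radii_mm[ax] < lo or o.center_mm[ax] + o.radii_mm[ax] > hi:
                    raise GenerationError(f"organ {o.name} does not fit inside the grid")
        for les in self.lesions:
            if les.uptake_suv <= self.background_suv:
                raise GenerationError("lesion uptake must exceed background uptake")

    def organ(self, name: str) -> OrganSpec:
        return next(o for o in self.organs if o.name == name)


@dataclass
class PhantomCase:
    """A generated phantom: images plus unambiguous ground truth."""

    ct: ImageVolume
    pet: ImageVolume
    organs: OrganMaskSet
    lesions: list[BinaryMask]
    truth_mtv_cm3: float
    spec: PhantomSpec
    seed: int
    ureter_mask: BinaryMask | None = None

    @property
    def grid(self) -> VoxelGrid:
        return self.ct.grid


def default_phantom_spec(
    grid: VoxelGrid | None = None,
    background_suv: float = 1.0,
    lesions: tuple[LesionSpec, ...] | None = None,
    ureter: UreterSpec | None = None,
    blur_fwhm_mm: float = 0.0,
    noise_sigma_suv: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """The stock whole-body layout: 96 x 96 x 160 voxels at 4 mm isotropic.

    The grid spans 384 x 384 x 640 mm; brain near the top, heart in the
    chest, kidneys flanking the midline in the mid-abdomen, bladder in the
    pelvis. Two avid lesions (SUV 8) sit in the axilla/chest wall region,
    clear of the organs and of the kidney-bladder corridor.
    """
    if grid is None:
        grid = VoxelGrid((96, 96, 160), (4.0, 4.0, 4.0))
    organs = (
        OrganSpec("brain", (192.0, 192.0, 576.0), (60.0, 70.0, 56.0), 45.0, 7.0),
        OrganSpec("heart", (210.0, 175.0, 440.0), (50.0, 55.0, 45.0), 55.0, 5.0),
        OrganSpec("kidney_left", (120.0, 215.0, 300.0), (26.0, 34.0, 48.0), 35.0, 6.0),
        OrganSpec("kidney_right", (264.0, 215.0, 300.0), (26.0, 34.0, 48.0), 35.0, 6.0),
        OrganSpec("bladder", (192.0, 210.0, 120.0), (36.0, 34.0, 30.0), 15.0, 15.0),
    )
    if lesions is None:
        lesions = (
            LesionSpec((110.0, 120.0, 420.0), 12.0, 8.0),
            LesionSpec((280.0, 140.0, 352.0), 15.0, 8.0),
        )
    return PhantomSpec(
        grid=grid,
        background_suv=background_suv,
        background_hu=0.0,
        organs=organs,
        lesions=tuple(lesions),
        ureter=ureter,
        blur_fwhm_mm=blur_fwhm_mm,
        noise_sigma_suv=noise_sigma_suv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Voxelization primitives
# ---------------------------------------------------------------------------

def _world_axes(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    return x, y, z


def voxelize_ellipsoid(grid: VoxelGrid, center: tuple[float, float, float],
                       radii: tuple[float, float, float]) -> np.ndarray:
    x, y, z = _world_axes(grid)
    d = ((x - center[0]) / radii[0]) ** 2 \
        + ((y - center[1]) / radii[1]) ** 2 \
        + ((z - center[2]) / radii[2]) ** 2
    return d <= 1.0


def voxelize_sphere(grid: VoxelGrid, center: tuple[float, float, float],
                    radius: float) -> np.ndarray:
    return voxelize_ellipsoid(grid, center, (radius, radius, radius))


def voxelize_capsule(grid: VoxelGrid, p0: np.ndarray, p1: np.ndarray,
                     radius: float) -> np.ndarray:
    """All voxels within ``radius`` mm of the segment p0 -> p1."""
    x, y, z = _world_axes(grid)
    d = p1 - p0
    dd = float(d @ d)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    if dd == 0.0:
        t = 0.0
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / dd, 0.0, 1.0)
    dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return dist2 <= radius ** 2


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _ureter_mask(spec: PhantomSpec) -> np.ndarray:
    """Two capsules from each kidney's medial-inferior aspect to the bladder.

    Like the renal pelvis, the tubes leave the kidney on its medial side
    (toward the body midline) before descending to the bladder dome.
    """
    assert spec.ureter is not None
    bl = spec.organ("bladder")
    target = np.array(bl.center_mm) + np.array([0.0, 0.0, 0.6 * bl.radii_mm[2]])
    midline_x = 0.5 * (spec.organ("kidney_left").center_mm[0]
                       + spec.organ("kidney_right").center_mm[0])
    out = np.zeros(spec.grid.shape, dtype=bool)
    for kname in ("kidney_left", "kidney_right"):
        k = spec.organ(kname)
        toward_mid = np.sign(midline_x - k.center_mm[0])
        start = np.array(k.center_mm) + np.array([
            toward_mid * 0.6 * k.radii_mm[0], 0.0, -0.85 * k.radii_mm[2]])
        out |= voxelize_capsule(spec.grid, start, target, spec.ureter.radius_mm)
    return out


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomCase:
    """Voxelize a phantom spec into a paired CT/PET case with ground truth.

    Identical (spec, seed) inputs yield bit-identical volumes. Structures
    that would make the truth ambiguous (organ/organ, lesion/organ,
    lesion/lesion or lesion/ureter overlap at voxel level) raise
    :class:`~petmtv.errors.GenerationError`.
    """
    if seed is None:
        seed = spec.seed
    grid = spec.grid
    ct = np.full(grid.shape, spec.background_hu, dtype=np.float32)
    pet = np.full(grid.shape, spec.background_suv, dtype=np.float32)

    organ_masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(grid.shape, dtype=bool)
    for o in spec.organs:
        m = voxelize_ellipsoid(grid, o.center_mm, o.radii_mm)
        if (m & occupied).any():
            raise GenerationError(f"organ {o.name} overlaps another organ")
        occupied |= m
        organ_masks[o.name] = m
        ct[m] = o.ct_hu
        pet[m] = o.pet_suv

    ureter = None
    if spec.ureter is not None:
        um = _ureter_mask(spec) & ~occupied  # tubes stop at the organ surfaces
        pet[um] = spec.ureter.suv
        ureter = BinaryMask(grid, um, label="ureter")
        occupied_for_lesions = occupied | um
    else:
        occupied_for_lesions = occupied

    lesion_masks: list[BinaryMask] = []
    taken = occupied_for_lesions.copy()
    for i, les in enumerate(spec.lesions):
        m = voxelize_sphere(grid, les.center_mm, les.radius_mm)
        if not m.any():
            raise GenerationError(f"lesion {i} voxelizes to zero voxels")
        if (m & taken).any():
            raise GenerationError(f"lesion {i} overlaps an organ, ureter or another lesion")
        taken |= m
        ct[m] = les.ct_hu
        pet[m] = les.uptake_suv
        lesion_masks.append(BinaryMask(grid, m, label=f"lesion_{i}"))

    truth_mtv = float(sum(m.volume_cm3 for m in lesion_masks))

    if spec.blur_fwhm_mm > 0:
        sigma_vox = [spec.blur_fwhm_mm / 2.3548200450309493 / s for s in grid.spacing]
        pet = ndimage.gaussian_filter(pet, sigma=sigma_vox).astype(np.float32)
    if spec.noise_sigma_suv > 0:
        rng = np.random.default_rng(seed)
        pet = pet + rng.normal(0.0, spec.noise_sigma_suv, size=grid.shape).astype(np.float32)
        np.clip(pet, 0.0, None, out=pet)

    organs = OrganMaskSet(**{
        name: BinaryMask(grid, organ_masks[name], label=name) for name in ORGAN_NAMES
    })
    return PhantomCase(
        ct=ImageVolume(grid, ct, modality="CT"),
        pet=ImageVolume(grid, pet, modality="PET"),
        organs=organs,
        lesions=lesion_masks,
        truth_mtv_cm3=truth_mtv,
        spec=spec,
        seed=seed,
        ureter_mask=ureter,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortVariation:
    """Per-case sampling ranges for a simulated patient cohort.

    ``None`` for the lesion fields keeps the base spec's lesion list
    unchanged (zero variation). Lesion centres are drawn uniformly inside
    the grid (with a margin), rejecting positions that overlap organs
    (padded by ``clearance_mm``), other lesions, or the kidney-bladder
    urinary corridor — the nodal stations this cohort emulates lie outside
    the urinary tract, whose uptake the method discards by design.
    """

    lesion_count: tuple[int, int] | None = (1, 5)
    lesion_radius_mm: tuple[float, float] | None = (8.0, 20.0)
    lesion_uptake_suv: tuple[float, float] | None = (6.0, 12.0)
    organ_jitter_mm: float = 4.0
    clearance_mm: float = 10.0
    edge_margin_mm: float = 28.0
    max_attempts: int = 500

    def is_zero(self) -> bool:
        return (
            self.lesion_count is None
            and self.lesion_radius_mm is None
            and self.lesion_uptake_suv is None
            and self.organ_jitter_mm == 0.0
        )

    def __post_init__(self) -> None:
        for rng_ in (self.lesion_count, self.lesion_radius_mm, self.lesion_uptake_suv):
            if rng_ is not None and rng_[1] < rng_[0]:
                raise ValueError(f"degenerate range {rng_}: high < low")
        if self.lesion_count is not None and self.lesion_count[0] < 0:
            raise ValueError("lesion count range must be nonnegative")
        if self.organ_jitter_mm < 0:
            raise ValueError("organ jitter must be >= 0")


def _corridor_box(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box around the kidney-bladder urinary corridor (mm)."""
    kl, kr, bl = (spec.organ(n) for n in ("kidney_left", "kidney_right", "bladder"))
    lo = np.array([
        min(kl.center_mm[0] - kl.radii_mm[0], bl.center_mm[0] - bl.radii_mm[0]),
        min(kl.center_mm[1] - kl.radii_mm[1], kr.center_mm[1] - kr.radii_mm[1],
            bl.center_mm[1] - bl.radii_mm[1]),
        bl.center_mm[2] - bl.radii_mm[2],
    ])
    hi = np.array([
        max(kr.center_mm[0] + kr.radii_mm[0], bl.center_mm[0] + bl.radii_mm[0]),
        max(kl.center_mm[1] + kl.radii_mm[1], kr.center_mm[1] + kr.radii_mm[1],
            bl.center_mm[1] + bl.radii_mm[1]),
        max(kl.center_mm[2] + kl.radii_mm[2], kr.center_mm[2] + kr.radii_mm[2]),
    ])
    return lo, hi


def _sphere_hits_box(center: np.ndarray, r: float, lo: np.ndarray, hi: np.ndarray) -> bool:
    nearest = np.clip(center, lo, hi)
    return float(np.sum((center - nearest) ** 2)) <= r * r


def _sphere_hits_ellipsoid(center: np.ndarray, r: float, o: OrganSpec, pad: float) -> bool:
    # conservative: scaled distance with padded radii
    rad = np.array(o.radii_mm) + r + pad
    d = (center - np.array(o.center_mm)) / rad
    return float(d @ d) <= 1.0


def _vary_spec(base: PhantomSpec, variation: CohortVariation, rng: np.random.Generator) -> PhantomSpec:
    organs = []
    for o in base.organs:
        jitter = rng.uniform(-variation.organ_jitter_mm, variation.organ_jitter_mm, 3) \
            if variation.organ_jitter_mm > 0 else np.zeros(3)
        organs.append(replace(o, center_mm=tuple(np.array(o.center_mm) + jitter)))
    spec = replace(base, organs=tuple(organs))

    if variation.lesion_count is None:
        return replace(spec, lesions=base.lesions)

    n_les = int(rng.integers(variation.lesion_count[0], variation.lesion_count[1] + 1))
    lo_box, hi_box = _corridor_box(spec)
    glo = np.array([spec.grid.extent(ax)[0] for ax in range(3)]) + variation.edge_margin_mm
    ghi = np.array([spec.grid.extent(ax)[1] for ax in range(3)]) - variation.edge_margin_mm
    lesions: list[LesionSpec] = []
    for _ in range(n_les):
        placed = False
        for _attempt in range(variation.max_attempts):
            r = float(rng.uniform(*variation.lesion_radius_mm)) if variation.lesion_radius_mm else 12.0
            u = float(rng.uniform(*variation.lesion_uptake_suv)) if variation.lesion_uptake_suv else 8.0
            c = rng.uniform(glo + r, ghi - r)
            if _sphere_hits_box(c, r + variation.clearance_mm, lo_box, hi_box):
                continue
            if any(_sphere_hits_ellipsoid(c, r, o, variation.clearance_mm) for o in spec.organs):
                continue
            if any(np.linalg.norm(c - np.array(l.center_mm)) <= r + l.radius_mm + variation.clearance_mm
                   for l in lesions):
                continue
            lesions.append(LesionSpec(tuple(c), r, u))
            placed = True
            break
        if not placed:
            raise GenerationError("could not place a lesion; ranges too tight for the grid")
    return replace(spec, lesions=tuple(lesions))


def iter_cohort(base_spec: PhantomSpec, n: int,
                variation: CohortVariation | None = None, seed: int = 0):
    """Yield ``n`` independently varied phantom cases (memory-light generator)."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    variation = variation if variation is not None else CohortVariation()
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        spec_i = _vary_spec(base_spec, variation, rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        yield generate_phantom(replace(spec_i, seed=noise_seed))


def generate_cohort(base_spec: PhantomSpec, n: int,
                    variation: CohortVariation | None = None, seed: int = 0) -> list[PhantomCase]:
    """Materialize :func:`iter_cohort` as a list."""
    return list(iter_cohort(base_spec, n, variation, seed))


# ---------------------------------------------------------------------------
# Labels and persistence
# ---------------------------------------------------------------------------

def labeled_case(case: PhantomCase) -> tuple[ImageVolume, np.ndarray]:
    """(CT, integer organ label map) pair for segmentation training."""
    return case.ct, case.organs.to_label_map()


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["grid"] = {"shape": spec.grid.shape, "spacing": spec.grid.spacing,
                 "origin": spec.grid.origin}
    return d


def spec_hash(spec: PhantomSpec) -> str:
    return hashlib.sha256(json.dumps(_spec_to_json(spec), sort_keys=True).encode()).hexdigest()[:12]


def write_case(case: PhantomCase, out_dir: str | os.PathLike, stem: str = "case") -> dict:
    """Write CT/PET NIfTI volumes, truth label maps and a JSON truth sidecar."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_volume(case.ct, os.path.join(out_dir, f"{stem}_ct.nii.gz"))
    write_volume(case.pet, os.path.join(out_dir, f"{stem}_pet.nii.gz"))
    write_label_map(case.grid, case.organs.to_label_map(),
                    os.path.join(out_dir, f"{stem}_organs.nii.gz"))
    lesion_labels = np.zeros(case.grid.shape, dtype=np.uint8)
    for i, m in enumerate(case.lesions, start=1):
        lesion_labels[m.membership] = i
    write_label_map(case.grid, lesion_labels, os.path.join(out_dir, f"{stem}_lesions.nii.gz"))
    sidecar = {
        "stem": stem,
        "seed": case.seed,
        "truth_mtv_cm3": case.truth_mtv_cm3,
        "lesion_volumes_cm3": [m.volume_cm3 for m in case.lesions],
        "lesion_suv": [l.uptake_suv for l in case.spec.lesions],
        "spec": _spec_to_json(case.spec),
        "spec_hash": spec_hash(case.spec),
    }
    with open(os.path.join(out_dir, f"{stem}_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
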