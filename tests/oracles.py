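"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (python loops, explicit
formulas) and deliberately shares no code with the package internals it
checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_resample_nearest(src_mask: np.ndarray, src_spacing, src_origin,
                           tgt_shape, tgt_spacing, tgt_origin) -> np.ndarray:
    """Per-voxel nearest-neighbour lookup over all target voxels."""
    out = np.zeros(tgt_shape, dtype=bool)
    for i in range(tgt_shape[0]):
        for j in range(tgt_shape[1]):
            for k in range(tgt_shape[2]):
                inside = True
                idx = []
                for ax, t in zip(range(3), (i, j, k)):
                    world = tgt_origin[ax] + t * tgt_spacing[ax]
                    s = int(round((world - src_origin[ax]) / src_spacing[ax]))
                    if s < 0 or s >= src_mask.shape[ax]:
                        inside = False
                        break
                    idx.append(s)
                if inside:
                    out[i, j, k] = src_mask[idx[0], idx[1], idx[2]]
    return out


def _neighbors(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def bfs_clusters(binary: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components by breadth-first search; list of voxel sets."""
    offs = _neighbors(connectivity)
    seen = np.zeros(binary.shape, dtype=bool)
    clusters = []
    nx, ny, nz = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offs:
                nx_, ny_, nz_ = x + dx, y + dy, z + dz
                if 0 <= nx_ < nx and 0 <= ny_ < ny and 0 <= nz_ < nz \
                        and binary[nx_, ny_, nz_] and not seen[nx_, ny_, nz_]:
                    seen[nx_, ny_, nz_] = True
                    q.append((nx_, ny_, nz_))
        clusters.append(comp)
    return clusters


def brute_zone_mask(kidney_left: np.ndarray, kidney_right: np.ndarray,
                    bladder: np.ndarray) -> np.ndarray | None:
    """Naive trapezoid zone: per-slice rectangles, bounds interpolated in z."""
    if not (kidney_left.any() and kidney_right.any() and bladder.any()):
        return None

    def centroid(mask, axis):
        pts = np.argwhere(mask)
        return pts[:, axis].mean()

    kz = np.argwhere(kidney_left | kidney_right)[:, 2]
    z_top = int(kz.max())
    z_bottom = int(round(centroid(bladder, 2)))
    if z_bottom > z_top:
        return None
    xl, xr = centroid(kidney_left, 0), centroid(kidney_right, 0)
    ky = np.argwhere(kidney_left | kidney_right)[:, 1]
    top = (min(xl, xr), max(xl, xr), ky.min(), ky.max())
    plane = bladder[:, :, z_bottom]
    if not plane.any():
        zs = sorted(set(np.argwhere(bladder)[:, 2]),
                    key=lambda z: abs(z - z_bottom))
        z_bottom = int(zs[0])
        plane = bladder[:, :, z_bottom]
    bx = np.argwhere(plane)[:, 0]
    by = np.argwhere(plane)[:, 1]
    bottom = (bx.min(), bx.max(), by.min(), by.max())

    out = np.zeros(kidney_left.shape, dtype=bool)
    for z in range(z_bottom, z_top + 1):
        t = 1.0 if z_top == z_bottom else (z - z_bottom) / (z_top - z_bottom)
        b = [bo + t * (to - bo) for to, bo in zip(top, bottom)]
        out[int(round(b[0])):int(round(b[1])) + 1,
            int(round(b[2])):int(round(b[3])) + 1, z] = True
    return out


def brute_mtv_loop(pet: np.ndarray, voxel_cm3: float,
                   organ_union: np.ndarray,
                   kidney_left: np.ndarray, kidney_right: np.ndarray,
                   bladder: np.ndarray,
                   fraction: float = 0.41, cand_min: float = 1.0,
                   lesion_min: float = 2.0, connectivity: int = 26,
                   zone_fraction: float = 0.5):
    """First-principles re-run of the whole iterative MTV loop.

    Returns (mtv_cm3, retained voxel-set list, thresholds per iteration).
    """
    zone = brute_zone_mask(kidney_left, kidney_right, bladder)
    space = ~organ_union.copy()
    thresholds = []
    for _ in range(1000):
        if not space.any():
            return 0.0, [], thresholds
        vals = np.where(space, pet, -np.inf)
        smax = vals.max()
        if smax <= 0:
            return 0.0, [], thresholds
        loc = np.unravel_index(int(np.argmax(vals)), pet.shape)
        thr = fraction * smax
        thresholds.append(thr)
        supra = space & (pet >= thr)
        clusters = bfs_clusters(supra, connectivity)
        hot = next(c for c in clusters if tuple(loc) in c)
        retained = []
        for c in clusters:
            vol = len(c) * voxel_cm3
            if vol <= cand_min:
                continue
            if vol < lesion_min:
                continue
            if zone is not None:
                inside = sum(1 for v in c if zone[v])
                if inside / len(c) > zone_fraction:
                    continue
            retained.append(c)
        if hot in retained:
            mtv = sum(len(c) for c in retained) * voxel_cm3
            return mtv, retained, thresholds
        for v in hot:
            space[v] = False
    raise RuntimeError("oracle loop did not terminate")


def icc2_closed_form(a: np.ndarray, b: np.ndarray):
    """Two-way random, absolute-agreement, single-rater ICC by mean squares.

    McGraw & Wong ICC(A,1) for n subjects, k=2 raters:
    (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)).
    """
    x = np.stack([a, b], axis=1).astype(float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
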