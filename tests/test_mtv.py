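"""MTV engine: trapezoid zone geometry, SUVmax, clustering vs BFS oracle,
screening rules and the iterative loop vs a first-principles oracle."""

import numpy as np
import pytest

from petmtv.core import BinaryMask, ImageVolume, OrganMaskSet, VoxelGrid
from petmtv.errors import DegenerateInputError, EmptySpaceError
from petmtv.mtv import (
    MTVParams,
    build_exclusion_zone,
    cluster_suprathreshold,
    compute_mtv,
    global_suvmax,
    screen_candidates,
)
from petmtv.phantom import LesionSpec, default_phantom_spec, generate_phantom

from tests.oracles import bfs_clusters, brute_mtv_loop


def _mask(grid, coords):
    m = np.zeros(grid.shape, bool)
    for c in coords:
        m[c] = True
    return BinaryMask(grid, m)


class TestZone:
    def test_top_base_spans_kidney_midlines(self, noiseless_case):
        organs = noiseless_case.organs
        zone = build_exclusion_zone(organs.kidney_left, organs.kidney_right,
                                    organs.bladder, noiseless_case.grid)
        # kidneys are centred at x = 120 mm and 264 mm -> voxels 30 and 66
        assert zone.top_bounds[0] == pytest.approx(30.0, abs=0.1)
        assert zone.top_bounds[1] == pytest.approx(66.0, abs=0.1)

    def test_midpoint_bounds_are_arithmetic_means(self, noiseless_case):
        organs = noiseless_case.organs
        zone = build_exclusion_zone(organs.kidney_left, organs.kidney_right,
                                    organs.bladder, noiseless_case.grid)
        zmid = (zone.z_top + zone.z_bottom) / 2.0
        for a, t, b in zip(zone.bounds_at(zmid), zone.top_bounds, zone.bottom_bounds):
            assert a == pytest.approx((t + b) / 2.0)

    def test_mask_confined_to_slab(self, noiseless_case):
        organs = noiseless_case.organs
        zone = build_exclusion_zone(organs.kidney_left, organs.kidney_right,
                                    organs.bladder, noiseless_case.grid)
        zs = np.flatnonzero(zone.mask.membership.any(axis=(0, 1)))
        assert zs.min() == zone.z_bottom
        assert zs.max() == zone.z_top

    def test_empty_mask_rejected(self, noiseless_case):
        organs = noiseless_case.organs
        empty = BinaryMask(noiseless_case.grid,
                           np.zeros(noiseless_case.grid.shape, bool))
        with pytest.raises(ValueError):
            build_exclusion_zone(empty, organs.kidney_right, organs.bladder)

    def test_bladder_above_kidneys_degenerate(self):
        grid = VoxelGrid((10, 10, 20), (4, 4, 4))
        kl = _mask(grid, [(2, 5, 5)])
        kr = _mask(grid, [(7, 5, 5)])
        bladder = _mask(grid, [(5, 5, 15)])
        with pytest.raises(DegenerateInputError):
            build_exclusion_zone(kl, kr, bladder, grid)


class TestGlobalSUVmax:
    grid = VoxelGrid((4, 4, 4), (4, 4, 4))

    def test_uniform_returns_first_space_voxel(self):
        pet = ImageVolume(self.grid, np.full(self.grid.shape, 3.0), "PET")
        space = BinaryMask(self.grid, np.ones(self.grid.shape, bool))
        val, loc = global_suvmax(pet, space)
        assert val == 3.0 and loc == (0, 0, 0)

    def test_single_hot_voxel(self):
        v = np.ones(self.grid.shape)
        v[2, 1, 3] = 12.5
        val, loc = global_suvmax(ImageVolume(self.grid, v, "PET"),
                                 BinaryMask(self.grid, np.ones(self.grid.shape, bool)))
        assert val == 12.5 and loc == (2, 1, 3)

    def test_tie_breaks_to_smallest_linear_index(self):
        v = np.ones(self.grid.shape)
        v[1, 0, 0] = 9.0
        v[3, 2, 1] = 9.0
        _, loc = global_suvmax(ImageVolume(self.grid, v, "PET"),
                               BinaryMask(self.grid, np.ones(self.grid.shape, bool)))
        assert loc == (1, 0, 0)

    def test_empty_space_signals(self):
        pet = ImageVolume(self.grid, np.ones(self.grid.shape), "PET")
        with pytest.raises(EmptySpaceError):
            global_suvmax(pet, BinaryMask(self.grid, np.zeros(self.grid.shape, bool)))

    def test_respects_space_mask(self):
        v = np.ones(self.grid.shape)
        v[0, 0, 0] = 50.0
        space = np.ones(self.grid.shape, bool)
        space[0, 0, 0] = False
        val, _ = global_suvmax(ImageVolume(self.grid, v, "PET"),
                               BinaryMask(self.grid, space))
        assert val == 1.0


class TestClustering:
    def test_no_supra_threshold_voxels(self):
        grid = VoxelGrid((5, 5, 5), (4, 4, 4))
        pet = ImageVolume(grid, np.ones(grid.shape), "PET")
        space = BinaryMask(grid, np.ones(grid.shape, bool))
        assert cluster_suprathreshold(pet, space, 5.0) == []

    def test_two_hot_spheres_give_two_clusters(self, noiseless_case):
        from petmtv.transfer import analysis_space

        space = analysis_space(noiseless_case.pet, noiseless_case.organs)
        clusters = cluster_suprathreshold(noiseless_case.pet, space, 7.5)
        assert len(clusters) == 2
        counts = sorted(c.mask.voxel_count for c in clusters)
        expected = sorted(m.voxel_count for m in noiseless_case.lesions)
        assert counts == expected

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bfs_oracle(self, connectivity, seed):
        grid = VoxelGrid((10, 10, 10), (4, 4, 4))
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 2, grid.shape)
        pet = ImageVolume(grid, v, "PET")
        space = BinaryMask(grid, rng.random(grid.shape) > 0.2)
        thr = 1.0
        clusters = cluster_suprathreshold(pet, space, thr, connectivity)
        expected = bfs_clusters(space.membership & (v >= thr), connectivity)
        got = sorted(frozenset(map(tuple, np.argwhere(c.mask.membership)))
                     for c in clusters)
        want = sorted(frozenset(c) for c in expected)
        assert got == want

    def test_cluster_suvmax_location_inside_mask(self, noiseless_case):
        from petmtv.transfer import analysis_space

        space = analysis_space(noiseless_case.pet, noiseless_case.organs)
        for c in cluster_suprathreshold(noiseless_case.pet, space, 7.5):
            assert c.mask.membership[c.suvmax_voxel]
            assert c.suvmax == pytest.approx(8.0)


class TestScreening:
    grid = VoxelGrid((20, 20, 20), (4, 4, 4))  # voxel = 0.064 cm3

    def _roi(self, n_vox, n_in_zone, zone_mask):
        from petmtv.mtv import LesionROI

        m = np.zeros(self.grid.shape, bool)
        placed = 0
        zone_idx = np.argwhere(zone_mask)
        for idx in zone_idx[:n_in_zone]:
            m[tuple(idx)] = True
            placed += 1
        free = np.argwhere(~zone_mask)
        for idx in free[:n_vox - placed]:
            m[tuple(idx)] = True
        return LesionROI(BinaryMask(self.grid, m),
                         volume_cm3=n_vox * self.grid.voxel_volume_cm3,
                         suvmax=5.0, suvmax_voxel=tuple(np.argwhere(m)[0]))

    def _zone(self):
        from petmtv.mtv import TrapezoidZone

        zm = np.zeros(self.grid.shape, bool)
        zm[5:15, 5:15, 5:15] = True
        return TrapezoidZone(BinaryMask(self.grid, zm), 14, 5,
                             (5, 14, 5, 14), (5, 14, 5, 14))

    def test_small_cluster_screened(self):
        zone = self._zone()
        roi = self._roi(23, 0, zone.mask.membership)  # 1.472 cm3 < 2 cm3
        retained, screened = screen_candidates([roi], zone, MTVParams())
        assert retained == [] and screened[0].status == "screened_small"

    def test_cluster_fully_in_zone_screened(self):
        zone = self._zone()
        roi = self._roi(63, 63, zone.mask.membership)  # 4.03 cm3, 100% in zone
        retained, screened = screen_candidates([roi], zone, MTVParams())
        assert retained == [] and screened[0].status == "screened_zone"

    def test_grazing_zone_overlap_retained(self):
        zone = self._zone()
        roi = self._roi(47, 5, zone.mask.membership)  # 3 cm3, ~10% in zone
        retained, screened = screen_candidates([roi], zone, MTVParams())
        assert screened == [] and retained[0].status == "retained"

    def test_any_overlap_rule(self):
        zone = self._zone()
        roi = self._roi(47, 5, zone.mask.membership)
        retained, screened = screen_candidates(
            [roi], zone, MTVParams(zone_rule="any_overlap"))
        assert retained == [] and screened[0].status == "screened_zone"


class TestComputeMTV:
    def test_noiseless_phantom_recovers_truth_exactly(self, noiseless_case):
        res = compute_mtv(noiseless_case.pet, noiseless_case.organs)
        assert res.mtv_cm3 == pytest.approx(noiseless_case.truth_mtv_cm3)
        assert res.suvmax == pytest.approx(8.0)
        assert len(res.retained) == len(noiseless_case.lesions)
        assert res.n_iterations == 1

    def test_mtv_conservation(self, noisy_case):
        from petmtv.transfer import transfer_contours

        organs_pet = transfer_contours(noisy_case.organs, noisy_case.pet)
        res = compute_mtv(noisy_case.pet, organs_pet)
        voxsum = sum(r.mask.voxel_count for r in res.retained)
        assert res.mtv_cm3 == pytest.approx(
            voxsum * noisy_case.grid.voxel_volume_cm3, abs=1e-9)

    def test_no_retained_roi_touches_organs(self, noisy_case):
        from petmtv.transfer import transfer_contours

        organs_pet = transfer_contours(noisy_case.organs, noisy_case.pet)
        res = compute_mtv(noisy_case.pet, organs_pet)
        union = organs_pet.union().membership
        for roi in res.retained:
            assert not (roi.mask.membership & union).any()

    def test_flat_pet_gives_zero_mtv(self, noiseless_case):
        pet = ImageVolume(noiseless_case.grid,
                          np.zeros(noiseless_case.grid.shape), "PET")
        res = compute_mtv(pet, noiseless_case.organs)
        assert res.mtv_cm3 == 0.0 and res.retained == []

    def test_thresholds_strictly_decrease(self):
        case = _zone_focus_case()
        res = compute_mtv(case.pet, case.organs)
        thresholds = [t.threshold for t in res.trace]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_loop_matches_brute_force_oracle(self, seed):
        pet, organs, params = _random_small_problem(seed)
        res = compute_mtv(pet, organs, params)
        mtv, retained, thresholds = brute_mtv_loop(
            np.asarray(pet.values), pet.grid.voxel_volume_cm3,
            organs.union().membership,
            organs.kidney_left.membership, organs.kidney_right.membership,
            organs.bladder.membership,
            cand_min=params.candidate_min_cm3, lesion_min=params.lesion_min_cm3,
            connectivity=params.connectivity)
        assert res.mtv_cm3 == pytest.approx(mtv, abs=1e-9)
        assert [t.threshold for t in res.trace] == pytest.approx(thresholds)


def _zone_focus_case():
    """Phantom whose hottest focus (SUV 12) sits inside the trapezoid zone."""
    lesions = (
        LesionSpec((192.0, 210.0, 200.0), 9.0, 12.0),  # urinary-corridor focus
        LesionSpec((280.0, 140.0, 352.0), 15.0, 8.0),  # true lesion
    )
    return generate_phantom(default_phantom_spec(lesions=lesions))


def test_zone_focus_hand_trace():
    """Hottest focus in the zone: removed in iteration 1 (threshold 4.92),
    re-thresholded at 3.28, MTV = remaining lesion volume."""
    case = _zone_focus_case()
    res = compute_mtv(case.pet, case.organs)
    assert res.n_iterations == 2
    assert [t.threshold for t in res.trace] == pytest.approx([4.92, 3.28])
    assert res.trace[0].removed_status == "screened_zone"
    assert res.mtv_cm3 == pytest.approx(case.lesions[1].volume_cm3)
    assert res.suvmax == pytest.approx(8.0)
    assert res.global_suvmax == pytest.approx(12.0)


def _random_small_problem(seed):
    """<= 12^3 grid with random uptake and simple organ boxes."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(8, 13, 3))
    grid = VoxelGrid(shape, (8.0, 8.0, 8.0))  # voxel 0.512 cm3
    v = rng.uniform(0, 2, shape)
    for _ in range(rng.integers(1, 4)):  # hot blobs
        c = rng.integers(1, np.array(shape) - 2)
        v[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2] += rng.uniform(3, 9)
    masks = {}
    organ_taken = np.zeros(shape, bool)

    def box(name, x0, y0, z0):
        m = np.zeros(shape, bool)
        m[x0, y0, z0] = True
        m &= ~organ_taken
        organ_taken[:] |= m
        masks[name] = BinaryMask(grid, m, name)

    nx, ny, nz = shape
    box("brain", 0, 0, nz - 1)
    box("heart", 1, 1, nz - 2)
    box("kidney_left", 1, ny // 2, nz // 2)
    box("kidney_right", nx - 2, ny // 2, nz // 2)
    box("bladder", nx // 2, ny // 2, 1)
    organs = OrganMaskSet(**masks)
    params = MTVParams(connectivity=int(rng.choice([6, 18, 26])))
    pet = ImageVolume(grid, v, "PET")
    return pet, organs, params
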