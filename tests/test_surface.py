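import numpy as np
import pytest
from scipy import ndimage

import rootct as rc
from rootct.surface import boundary_mask

from conftest import digital_ball_mask


def _volume(data, vs=0.05):
    return rc.VoxelVolume(np.asarray(data, np.uint16), vs)


def _example_from_means(vol, bg_coord, mat_coord):
    return rc.MaterialExample.from_volume(vol, [bg_coord], [mat_coord])


class TestDefineMaterialByExample:
    @pytest.mark.parametrize("bg,mat,brighter", [(1000, 30000, True),
                                                 (30000, 1000, False)])
    def test_midpoint_threshold_and_orientation(self, bg, mat, brighter):
        data = np.zeros((2, 2, 2), np.uint16)
        data[0, 0, 0] = bg
        data[1, 1, 1] = mat
        ex = _example_from_means(_volume(data), (0, 0, 0), (1, 1, 1))
        res = rc.define_material_by_example(_volume(data), ex)
        assert res.threshold == pytest.approx(15500)
        assert res.material_brighter is brighter

    def test_equal_means_rejected(self):
        data = np.full((2, 2, 2), 5, np.uint16)
        with pytest.raises(ValueError, match="equal"):
            _example_from_means(_volume(data), (0, 0, 0), (1, 1, 1))

    def test_disjointness_required(self):
        data = np.zeros((2, 2, 2), np.uint16)
        with pytest.raises(ValueError):
            rc.MaterialExample.from_volume(_volume(data), [(0, 0, 0)], [(0, 0, 0)])

    def test_near_optimal_on_two_gaussian_phantom(self, rng):
        # the example-midpoint threshold must misclassify at most 1 % more
        # than the best threshold found by brute-force sweep
        labels = rng.uniform(size=(24, 24, 24)) < 0.5
        gray = np.where(labels, rng.normal(40000, 1500, labels.shape),
                        rng.normal(8000, 1500, labels.shape))
        vol = _volume(np.clip(gray, 0, 65535))
        mat_coords = np.argwhere(labels)[rng.choice(labels.sum(), 100, replace=False)]
        bg_coords = np.argwhere(~labels)[rng.choice((~labels).sum(), 100, replace=False)]
        ex = rc.MaterialExample.from_volume(vol, bg_coords, mat_coords)
        thr = rc.define_material_by_example(vol, ex).threshold
        data = vol.data.astype(float)
        err = ((data >= thr) != labels).mean()
        sweep = np.linspace(data.min(), data.max(), 2000)
        best = min(((data >= t) != labels).mean() for t in sweep)
        assert err <= best + 0.01


class TestMaskBoundary:
    def test_cube_shell(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        coords = rc.mask_boundary(rc.ROIMask(m, 0.05), connectivity=26)
        assert len(coords) == 26
        assert (2, 2, 2) not in {tuple(c) for c in coords}

    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        coords = rc.mask_boundary(rc.ROIMask(m, 0.05))
        assert {tuple(c) for c in coords} == {(1, 1, 1)}

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bruteforce_neighbor_enumeration(self, rng, connectivity):
        m = rng.uniform(size=(20, 20, 20)) < 0.3
        offsets = [(dz, dy, dx)
                   for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                   if (dz, dy, dx) != (0, 0, 0)
                   and (connectivity == 26 or abs(dz) + abs(dy) + abs(dx) == 1)]
        expected = set()
        for z, y, x in np.argwhere(m):
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if not all(0 <= p[i] < 20 for i in range(3)) or not m[p]:
                    expected.add((z, y, x))
                    break
        got = {tuple(c) for c in rc.mask_boundary(rc.ROIMask(m, 0.05), connectivity)}
        assert got == expected


def _blurred_step_volume(nx=40, edge=20.0, sigma=2.0, lo=5000.0, hi=30000.0):
    x = np.arange(nx, dtype=float)
    from scipy.special import erf
    profile = lo + (hi - lo) * 0.5 * (1 + erf((x - edge) / (np.sqrt(2) * sigma)))
    data = np.broadcast_to(profile[None, None, :], (16, 16, nx)).copy()
    return _volume(np.clip(data, 0, 65535))


class TestAdvancedSurfaceDetermination:
    def test_uniform_below_threshold_gives_empty_mask(self):
        vol = _volume(np.full((8, 8, 8), 100, np.uint16))
        mask = rc.advanced_surface_determination(vol, None, 100.0)
        assert mask.voxel_count() == 0

    def test_threshold_outside_range_rejected(self):
        vol = _volume(np.full((8, 8, 8), 100, np.uint16))
        with pytest.raises(ValueError, match="outside"):
            rc.advanced_surface_determination(vol, None, 60000.0)

    def test_step_edge_relocated_to_true_edge(self):
        # threshold chosen so the naive boundary sits ~2-3 voxels into the
        # bright side; the refined boundary must come back to the edge at x = 20
        vol = _blurred_step_volume()
        biased_thr = float(vol.data[0, 0, 22])
        mask = rc.advanced_surface_determination(vol, None, biased_thr)
        rows = mask.data[2:-2, 2:-2, :]
        first_x = np.argmax(rows, axis=-1)
        assert np.all(np.abs(first_x - 20) <= 1)

    def test_biased_ball_volume_recovered(self):
        z, y, x = np.mgrid[:48, :48, :48]
        rho = np.sqrt((z - 23.5)**2 + (y - 23.5)**2 + (x - 23.5)**2)
        gray = ndimage.gaussian_filter(np.where(rho <= 12.0, 40000.0, 5000.0), 1.0)
        vol = _volume(gray)
        # threshold at the blurred intensity ~2 voxels outside the surface,
        # inflating the naive mask accordingly
        biased_thr = float(gray[tuple(np.argwhere(np.abs(rho - 14.0) < 0.05)[0])])
        mask = rc.advanced_surface_determination(vol, None, biased_thr)
        analytic = 4 / 3 * np.pi * 12**3
        assert mask.voxel_count() == pytest.approx(analytic, rel=0.03)

    def test_refinement_is_conservative(self):
        # the refined mask may differ from the thresholded mask only within
        # search_distance of the initial boundary
        vol = _blurred_step_volume()
        params = rc.SurfaceDeterminationParams()
        thr = float(vol.data[0, 0, 23])
        mask = rc.advanced_surface_determination(vol, None, thr, params)
        m0 = vol.data > thr
        changed = mask.data != m0
        dist_to_bnd = ndimage.distance_transform_edt(~boundary_mask(m0, 26))
        assert dist_to_bnd[changed].max() <= params.search_distance_voxels + 1

    def test_result_insensitive_to_threshold_bias(self):
        # the refined surface must land within 1 voxel of the true edge no
        # matter whether the threshold is biased inward or outward by 2 voxels
        z, y, x = np.mgrid[:40, :40, :40]
        rho = np.sqrt((z - 19.5)**2 + (y - 19.5)**2 + (x - 19.5)**2)
        gray = ndimage.gaussian_filter(np.where(rho <= 10.0, 40000.0, 5000.0), 1.0)
        vol = _volume(gray)
        # 1 voxel of surface placement tolerance plus half a voxel of mask
        # rounding on either side
        for bias in (-2.0, 2.0):
            thr = float(gray[tuple(np.argwhere(np.abs(rho - (10 + bias)) < 0.06)[0])])
            mask = rc.advanced_surface_determination(vol, None, thr).data
            assert mask[rho <= 8.5].all()        # interior always material
            assert not mask[rho >= 11.5].any()   # exterior always background

    def test_determinism(self):
        vol = _blurred_step_volume()
        thr = float(vol.data[0, 0, 22])
        a = rc.advanced_surface_determination(vol, None, thr)
        b = rc.advanced_surface_determination(vol, None, thr)
        np.testing.assert_array_equal(a.data, b.data)

    def test_domain_restriction(self):
        vol = _blurred_step_volume()
        dom = np.zeros(vol.shape, bool)
        dom[:, :8, :] = True
        mask = rc.advanced_surface_determination(
            vol, rc.ROIMask(dom, vol.voxel_size_mm), 17000.0)
        assert not mask.data[:, 8:, :].any()

    def test_empty_domain_rejected(self):
        vol = _blurred_step_volume()
        with pytest.raises(ValueError, match="empty"):
            rc.advanced_surface_determination(
                vol, rc.ROIMask(np.zeros(vol.shape, bool), 0.05), 17000.0)
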